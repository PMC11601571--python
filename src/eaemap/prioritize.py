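"""Network-based candidate-gene prioritization with an SVM ensemble.

Positional candidates under a QTL are ranked by how similar their
tissue-specific functional-network connectivity is to that of known
trait-associated genes.  The feature vector of a gene is its vector of
connection weights to the positive (trait-associated) training genes; an
ensemble of linear SVMs is trained, each against a fresh random draw of
negative genes, and each candidate is scored by its false positive rate

    FPR_x = FP / (FP + TN)

among that round's negatives at a decision-value cutoff equal to the
candidate's own, averaged across the ensemble.  The final score is
-log10 of the averaged FPR; candidates with mean FPR <= 0.05 are called
significant.  Also provided: ortholog-mapped gene-list overlap and the
nonsynonymous-variant founder-segregation filter used to shortlist
coding candidates within a QTL interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .genomescan import FOUNDERS

logger = logging.getLogger(__name__)

FPR_CUTOFF = 0.05
DEFAULT_N_SVM = 100

#: consequence strings accepted as nonsynonymous
_NONSYN = {"missense", "missense_variant", "nonsynonymous", "nonsynonymous_variant"}


class GeneNetwork:
    """Weighted undirected gene-gene functional network for one tissue."""

    def __init__(self, graph: nx.Graph, tissue: str = ""):
        for u, v, w in graph.edges.data("weight"):
            if u == v:
                raise ValueError(f"self-edge on {u}")
            if w is None or not np.isfinite(w) or w < 0:
                raise ValueError(f"bad weight on edge ({u}, {v}): {w}")
        self.graph = graph
        self.tissue = tissue

    @property
    def genes(self):
        return set(self.graph.nodes)

    def __contains__(self, gene):
        return gene in self.graph

    @classmethod
    def from_edges(cls, edges, tissue: str = "") -> "GeneNetwork":
        """Build from an iterable of (gene_a, gene_b, weight)."""
        g = nx.Graph()
        g.add_weighted_edges_from(edges)
        return cls(g, tissue)

    @classmethod
    def read(cls, path, tissue: str = "") -> "GeneNetwork":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = list(df.columns[:3])
        return cls.from_edges(
            df[cols].itertuples(index=False, name=None), tissue=tissue
        )

    def write(self, path, sep="\t"):
        rows = [(u, v, w) for u, v, w in self.graph.edges.data("weight")]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
            path, sep=sep, index=False
        )


@dataclass
class TrainingSet:
    """Positive trait genes, the negative pool, and withheld candidates."""

    positives: list
    negative_pool: list
    removed_candidates: list = field(default_factory=list)

    def __post_init__(self):
        pos, neg = set(self.positives), set(self.negative_pool)
        if pos & neg:
            raise ValueError(f"positives overlap negative pool: {sorted(pos & neg)[:5]}")
        if set(self.removed_candidates) & pos:
            raise ValueError("candidates must be removed from positives before training")


@dataclass
class Ensemble:
    """A trained SVM ensemble with its per-round negative draws."""

    models: list
    negative_sets: list  # per round, list of gene labels
    feature_genes: list  # column order of the feature table used in training
    features: pd.DataFrame  # features of the training universe (pos + pool)


def build_features(
    network: GeneNetwork,
    positives: Sequence[str],
    genes_to_score: Sequence[str],
):
    """Connection-weight feature table and the list of trimmed genes.

    Each row gene g gets the vector of edge weights from g to each
    positive training gene (0 where no edge; a positive's weight to
    itself is 0).  Genes whose vectors are all zero carry no network
    information and are trimmed; because trimming a positive removes a
    feature column, the trim is iterated to a fixed point.

    Returns (features, kept_positives, trimmed) where ``features`` is
    indexed by gene with one column per kept positive.
    """
    missing = [p for p in positives if p not in network]
    if missing:
        raise ValueError(f"positives absent from network: {missing[:10]}")
    adj = network.graph.adj
    kept = list(positives)
    while True:
        weights = [adj[p] for p in kept]
        alive = [
            p
            for p, nbrs in zip(kept, weights)
            if any(q != p and q in nbrs and nbrs[q].get("weight", 0.0) > 0 for q in kept)
        ]
        if len(alive) == len(kept):
            break
        kept = alive
    kept_set = set(kept)

    all_genes = list(dict.fromkeys(list(genes_to_score)))
    mat = np.zeros((len(all_genes), len(kept)))
    col = {p: j for j, p in enumerate(kept)}
    for i, g in enumerate(all_genes):
        if g not in network:
            continue
        for q, data in adj[g].items():
            j = col.get(q)
            if j is not None and q != g:
                mat[i, j] = data.get("weight", 0.0)
    features = pd.DataFrame(mat, index=all_genes, columns=kept)
    connected = features.to_numpy().any(axis=1)
    trimmed = [g for g, ok in zip(all_genes, connected) if not ok]
    trimmed += [p for p in positives if p not in kept_set and p not in set(trimmed)]
    features = features.loc[connected]
    if trimmed:
        logger.info("trimmed %d unconnected genes", len(trimmed))
    return features, kept, trimmed


def train_ensemble(
    features: pd.DataFrame,
    training: TrainingSet,
    n_svm: int = DEFAULT_N_SVM,
    seed: int = 0,
    C: float = 1.0,
) -> Ensemble:
    """Train ``n_svm`` linear SVMs, each against a fresh negative draw.

    Every round samples |positives| negatives without replacement from
    the negative pool and fits a maximum-margin linear classifier
    (positives labeled 1) on raw connection weights.
    """
    pos = [p for p in training.positives if p in features.index]
    pool = [g for g in training.negative_pool if g in features.index]
    if len(pool) < len(pos):
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than positives ({len(pos)})"
        )
    rng = np.random.default_rng(seed)
    Xpos = features.loc[pos].to_numpy()
    models, neg_sets = [], []
    pool_arr = np.array(pool, dtype=object)
    for _ in range(n_svm):
        negs = list(pool_arr[rng.choice(len(pool_arr), size=len(pos), replace=False)])
        X = np.vstack([Xpos, features.loc[negs].to_numpy()])
        y = np.r_[np.ones(len(pos)), np.zeros(len(negs))]
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, y)
        models.append(clf)
        neg_sets.append(negs)
    return Ensemble(models=models, negative_sets=neg_sets, feature_genes=pos, features=features)


def fpr(candidate_score: float, negative_scores) -> float:
    """False positive rate at a cutoff equal to the candidate's score.

    FP counts negatives scoring at or above the candidate (a tie sits on
    the positive side of its own cutoff); TN counts the rest.
    """
    neg = np.asarray(negative_scores, dtype=float)
    if neg.size == 0:
        raise ValueError("negative_scores is empty")
    fp = int((neg >= candidate_score).sum())
    return fp / neg.size


def score_candidates(
    ensemble: Ensemble,
    candidate_features: pd.DataFrame,
    tissue: str = "",
    cutoff: float = FPR_CUTOFF,
) -> pd.DataFrame:
    """Score candidates against every SVM round; average the FPRs.

    Per round, the candidate's decision value is compared with the
    decision values of that round's own sampled negatives.  The final
    score is -log10(mean FPR), floored at 1/(n_rounds * m + 1) with m
    negatives per round so a candidate beating every negative in every
    round stays finite.  Candidates absent from the feature table (all
    connections trimmed) are returned as unrankable.
    """
    n_rounds = len(ensemble.models)
    m = len(ensemble.negative_sets[0]) if n_rounds else 0
    floor = 1.0 / (n_rounds * m + 1)
    rows = []
    scorable = candidate_features
    fprs = np.zeros((len(scorable), n_rounds))
    Xc = scorable.to_numpy()
    for r, (clf, negs) in enumerate(zip(ensemble.models, ensemble.negative_sets)):
        dvals_c = clf.decision_function(Xc)
        dvals_n = clf.decision_function(ensemble.features.loc[negs].to_numpy())
        for i, dc in enumerate(dvals_c):
            fprs[i, r] = fpr(dc, dvals_n)
    mean_fpr = fprs.mean(axis=1) if n_rounds else np.full(len(scorable), np.nan)
    for i, gene in enumerate(scorable.index):
        mf = float(mean_fpr[i])
        rows.append(
            {
                "gene": gene,
                "tissue": tissue,
                "mean_fpr": mf,
                "final_score": -np.log10(max(mf, floor)),
                "significant": mf <= cutoff,
                "unrankable": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "tissue", "mean_fpr", "final_score", "significant", "unrankable"],
    )


def prioritize_qtl(
    network: GeneNetwork,
    positives: Sequence[str],
    negative_pool: Sequence[str],
    candidates: Sequence[str],
    n_svm: int = DEFAULT_N_SVM,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end prioritization of one candidate list in one tissue.

    Candidates are removed from the training sets, features are built and
    trimmed, the ensemble is trained, and candidates are scored;
    unrankable (trimmed) candidates appear with NaN scores.
    """
    cand = list(dict.fromkeys(candidates))
    pos = [p for p in positives if p not in set(cand)]
    pool = [g for g in negative_pool if g not in set(cand) and g not in set(pos)]
    universe = pos + pool + cand
    features, kept_pos, trimmed = build_features(network, pos, universe)
    training = TrainingSet(positives=kept_pos,
                           negative_pool=[g for g in pool if g in features.index],
                           removed_candidates=cand)
    ensemble = train_ensemble(features, training, n_svm=n_svm, seed=seed)
    scorable = features.loc[[c for c in cand if c in features.index]]
    out = score_candidates(ensemble, scorable, tissue=network.tissue)
    unrank = [c for c in cand if c not in features.index]
    if unrank:
        out = pd.concat(
            [
                out,
                pd.DataFrame(
                    {
                        "gene": unrank,
                        "tissue": network.tissue,
                        "mean_fpr": np.nan,
                        "final_score": np.nan,
                        "significant": False,
                        "unrankable": True,
                    }
                ),
            ],
            ignore_index=True,
        )
    return out.sort_values("final_score", ascending=False, na_position="last").reset_index(
        drop=True
    )


def overlap_gene_lists(
    qtl_genes: dict,
    reference_lists: dict,
    orthology: pd.DataFrame,
) -> pd.DataFrame:
    """Intersect QTL positional genes with reference gene lists.

    ``qtl_genes`` maps QTL name -> mouse gene labels; ``reference_lists``
    maps list name -> human gene labels; ``orthology`` is a two-column
    (mouse, human) table.  Returns rows (qtl, mouse_gene, human_gene,
    list_name) for every ortholog-translated hit.
    """
    if orthology.shape[1] < 2:
        raise ValueError("orthology map must have two columns (mouse, human)")
    mcol, hcol = orthology.columns[:2]
    m2h = {}
    for m, h in zip(orthology[mcol], orthology[hcol]):
        m2h.setdefault(m, set()).add(h)
    rows = []
    for qtl, genes in qtl_genes.items():
        for g in genes:
            for h in sorted(m2h.get(g, ())):
                for name, ref in reference_lists.items():
                    if h in set(ref):
                        rows.append(
                            {"qtl": qtl, "mouse_gene": g, "human_gene": h, "list_name": name}
                        )
    return pd.DataFrame(rows, columns=["qtl", "mouse_gene", "human_gene", "list_name"])


def nssnp_segregating(
    variants: pd.DataFrame,
    interval,
    founder_a: str,
    founder_b: str,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Nonsynonymous variants whose alleles differ between two founders.

    ``interval`` is (chrom, lo_Mb, hi_Mb), closed.  Rows are kept iff the
    consequence is nonsynonymous/missense, the two named founders carry
    different alleles, the position lies inside the interval, and (if
    given) the gene is in ``genes``.
    """
    for f in (founder_a, founder_b):
        if f not in FOUNDERS:
            raise ValueError(f"unknown founder {f!r}; expected one of {FOUNDERS}")
        if f not in variants.columns:
            raise ValueError(f"variant table lacks allele column {f!r}")
    chrom, lo, hi = interval
    cons = variants["consequence"].astype(str).str.lower()
    mask = (
        cons.isin(_NONSYN)
        & (variants["chrom"].astype(str) == str(chrom))
        & (variants["pos_Mb"] >= lo)
        & (variants["pos_Mb"] <= hi)
        & (variants[founder_a] != variants[founder_b])
    )
    if genes is not None:
        mask &= variants["gene"].isin(set(genes))
    return variants[mask].reset_index(drop=True)
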