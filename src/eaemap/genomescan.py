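"""Haplotype-regression QTL scans on 8-founder genotype probabilities.

Implements the mapping chain used for multiparent recombinant inbred
panels such as the Collaborative Cross: rank-based inverse normal
transformation of phenotypes, batch residualization, marker-by-marker
regression of the phenotype on the 8 founder ancestry dosages
(LOD = (n/2) * log10(RSS0 / RSS1), the Haley-Knott form), genome-wide
significance thresholds from phenotype permutations, founder allele
effects under a sum-to-zero constraint, Bayesian credible intervals for
peaks, and genotype-by-phenotype tables.  An optional kinship correction
rotates the model by the eigendecomposition of a dosage-derived
genomic relationship matrix, with variance components estimated once
under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: Canonical founder strain order for the 8 Collaborative Cross founders.
FOUNDERS = ("AJ", "B6", "S129", "NOD", "NZO", "CAST", "PWK", "WSB")
N_FOUNDERS = len(FOUNDERS)

DEFAULT_ALPHAS = (0.15, 0.20)

#: Relative floor on RSS1, preventing infinite LOD on exact fits.
RSS_FLOOR_REL = 1e-12


class GenotypeProbs:
    """Founder-ancestry dosages: strains x markers x 8 founders.

    Each strain/marker 8-vector is nonnegative and sums to 1; marker
    positions are nondecreasing within a chromosome.
    """

    def __init__(self, strains: Sequence[str], markers: pd.DataFrame, probs: np.ndarray):
        self.strains = list(strains)
        self.markers = markers.reset_index(drop=True)  # columns: marker, chrom, pos_Mb
        self.probs = np.asarray(probs, dtype=float)
        self._validate()

    def _validate(self):
        S, M = len(self.strains), len(self.markers)
        if self.probs.shape != (S, M, N_FOUNDERS):
            raise ValueError(f"probs shape {self.probs.shape} != ({S}, {M}, {N_FOUNDERS})")
        for col in ("marker", "chrom", "pos_Mb"):
            if col not in self.markers.columns:
                raise ValueError(f"marker table missing column {col!r}")
        if self.probs.min() < -1e-9:
            raise ValueError("negative founder dosage")
        sums = self.probs.sum(axis=2)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("founder dosages do not sum to 1")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_Mb"].to_numpy()) < 0):
                raise ValueError(f"positions decrease on chromosome {chrom}")

    @property
    def n_strains(self):
        return len(self.strains)

    @property
    def n_markers(self):
        return len(self.markers)

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(idx[0])

    def chrom_slice(self, chrom) -> np.ndarray:
        return self.markers.index[self.markers["chrom"] == chrom].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Wide long-format table: one row per strain x marker."""
        S, M = self.n_strains, self.n_markers
        base = self.markers.loc[np.tile(np.arange(M), S)].reset_index(drop=True)
        base.insert(0, "strain", np.repeat(self.strains, M))
        for f_i, f in enumerate(FOUNDERS):
            base[f] = self.probs[:, :, f_i].reshape(-1)
        return base

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeProbs":
        need = ["strain", "chrom", "pos_Mb", "marker", *FOUNDERS]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"genotype table missing columns {missing}")
        markers = (
            df[["marker", "chrom", "pos_Mb"]]
            .drop_duplicates("marker")
            .reset_index(drop=True)
        )
        strains = list(dict.fromkeys(df["strain"]))
        m_idx = {m: i for i, m in enumerate(markers["marker"])}
        s_idx = {s: i for i, s in enumerate(strains)}
        probs = np.zeros((len(strains), len(markers), N_FOUNDERS))
        rows_s = df["strain"].map(s_idx).to_numpy()
        rows_m = df["marker"].map(m_idx).to_numpy()
        probs[rows_s, rows_m] = df[list(FOUNDERS)].to_numpy(dtype=float)
        return cls(strains, markers, probs)

    def write(self, path, sep="\t"):
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path) -> "GenotypeProbs":
        return cls.from_frame(pd.read_csv(path, sep=None, engine="python"))


@dataclass
class PhenotypeVector:
    """A phenotype measured per mouse or per strain.

    ``strain_of`` maps each unit (row of ``values``) to a strain label
    present in the genotype table; for strain-level phenotypes it is the
    strain labels themselves.
    """

    values: np.ndarray
    strain_of: np.ndarray
    unit: str = "strain"  # or "mouse"
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.strain_of = np.asarray(self.strain_of, dtype=object)
        if len(self.values) != len(self.strain_of):
            raise ValueError("values and strain_of length mismatch")
        if self.unit not in ("mouse", "strain"):
            raise ValueError("unit must be 'mouse' or 'strain'")


@dataclass
class ScanResult:
    """Genome-scan output: per-marker LOD plus thresholds, peaks, effects."""

    lod: pd.DataFrame  # columns: marker, chrom, pos_Mb, lod
    n: int
    thresholds: dict = field(default_factory=dict)  # alpha -> LOD
    peaks: pd.DataFrame = None
    effects: dict = field(default_factory=dict)  # peak marker -> 8 founder effects


# ---------------------------------------------------------------------------
# phenotype preprocessing


def rank_z(values) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((r - 0.5)/n).

    Average ranks for ties.  All-identical input returns zeros with a
    warning (no ordering information to normalize).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("rank_z requires at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("rank_z requires finite values")
    if np.ptp(x) == 0:
        warnings.warn("rank_z: all values identical; returning zeros")
        return np.zeros_like(x)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.5) / x.size)


def residualize_batch(values, batch) -> np.ndarray:
    """Residuals of least squares on batch indicator covariates.

    Equivalent to subtracting each batch's mean; per-batch residual means
    are 0.  A single batch reduces to grand-mean centering; a singleton
    batch yields a 0 residual (and a warning).
    """
    x = np.asarray(values, dtype=float)
    batch = np.asarray(batch)
    if len(x) != len(batch):
        raise ValueError("values and batch length mismatch")
    out = np.empty_like(x)
    for b in np.unique(batch):
        mask = batch == b
        if mask.sum() == 1:
            warnings.warn(f"batch {b!r} has a single observation; residual forced to 0")
        out[mask] = x[mask] - x[mask].mean()
    return out


def preprocess_phenotype(values, batch=None) -> np.ndarray:
    """Standard mapping transform: batch residualization, then rank-Z."""
    x = np.asarray(values, dtype=float)
    if batch is not None:
        x = residualize_batch(x, batch)
    return rank_z(x)


# ---------------------------------------------------------------------------
# kinship


def compute_kinship(probs: GenotypeProbs, loco: bool = False):
    """Genomic relationship matrix from founder dosages.

    K = (1/M) * sum_m D_m D_m^T over markers, rescaled to unit average
    diagonal.  With ``loco=True`` returns {chrom: K excluding that
    chromosome} (leave-one-chromosome-out).
    """
    if probs.n_markers == 0:
        raise ValueError("no markers")

    def _k(marker_idx):
        D = probs.probs[:, marker_idx, :]  # (S, m, 8)
        K = np.einsum("smf,tmf->st", D, D) / D.shape[1]
        avg_diag = np.trace(K) / K.shape[0]
        if avg_diag > 0:
            K = K / avg_diag
        return K

    if not loco:
        return _k(np.arange(probs.n_markers))
    out = {}
    for chrom in pd.unique(probs.markers["chrom"]):
        keep = probs.markers.index[probs.markers["chrom"] != chrom].to_numpy()
        if keep.size == 0:
            raise ValueError(f"LOCO kinship for {chrom}: no markers left")
        out[chrom] = _k(keep)
    return out


def _expand_kinship(K: np.ndarray, strain_idx: np.ndarray) -> np.ndarray:
    return K[np.ix_(strain_idx, strain_idx)]


def _null_h2(y: np.ndarray, K: np.ndarray) -> float:
    """ML estimate of the heritability-like variance ratio under the null."""
    lam, V = np.linalg.eigh(K)
    lam = np.clip(lam, 0, None)
    yr = V.T @ y
    onesr = V.T @ np.ones_like(y)
    n = y.size

    def negll(h2):
        d = h2 * lam + (1 - h2)
        w = 1.0 / d
        b = (onesr * w) @ yr / ((onesr * w) @ onesr)
        rss = w @ (yr - b * onesr) ** 2
        return 0.5 * (n * np.log(rss / n) + np.log(d).sum())

    res = minimize_scalar(negll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    return float(res.x)


def _whitener(K: np.ndarray, h2: float) -> np.ndarray:
    """W such that Cov(W e) = I under Var(e) = h2*K + (1-h2)*I."""
    lam, V = np.linalg.eigh(K)
    lam = np.clip(lam, 0, None)
    d = h2 * lam + (1 - h2)
    return (V / np.sqrt(d)) @ V.T  # symmetric inverse square root


# ---------------------------------------------------------------------------
# the scan


def _expand_units(probs: GenotypeProbs, phenotype: PhenotypeVector):
    s_idx = {s: i for i, s in enumerate(probs.strains)}
    missing = sorted({s for s in phenotype.strain_of if s not in s_idx})
    if missing:
        raise ValueError(f"phenotype strains not in genotype table: {missing}")
    return np.array([s_idx[s] for s in phenotype.strain_of])


def _design_tensor(G: np.ndarray) -> np.ndarray:
    """(n, M, 8) design per marker: intercept + 7 founder dosages.

    The last founder's dosage column is dropped for identifiability
    (dosages sum to 1 against the intercept).
    """
    n, M, _ = G.shape
    X = np.empty((n, M, N_FOUNDERS))
    X[:, :, 0] = 1.0
    X[:, :, 1:] = G[:, :, : N_FOUNDERS - 1]
    return X


def _marker_rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RSS of per-marker least squares, batched over phenotype columns.

    X: (n, M, k) designs; Y: (n, P).  Returns (M, P).  Uses the projection
    identity RSS = ||y||^2 - b^T A^+ b with A = X^T X, b = X^T y, which is
    exact for rank-deficient designs (collinear dosage columns are
    implicitly dropped by the pseudoinverse).
    """
    A = np.einsum("nmi,nmj->mij", X, X)
    B = np.einsum("nmi,np->mip", X, Y)
    Ainv = np.linalg.pinv(A, hermitian=True)
    yty = np.einsum("np,np->p", Y, Y)
    explained = np.einsum("mip,mij,mjp->mp", B, Ainv, B)
    return yty[None, :] - explained


def _lod_matrix(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """(M, P) LOD scores of Y columns against marker dosages G."""
    n = Y.shape[0]
    X = _design_tensor(G)
    rss1 = _marker_rss(X, Y)
    ybar = Y.mean(axis=0)
    rss0 = ((Y - ybar) ** 2).sum(axis=0)
    var = rss0 / n
    floor = np.maximum(RSS_FLOOR_REL * var * n, np.finfo(float).tiny)
    rss1 = np.maximum(rss1, floor[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(np.maximum(rss0[None, :], floor[None, :]) / rss1)
    return np.clip(lod, 0.0, None)


def _lod_matrix_whitened(G: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """LOD after whitening rows by W (kinship-rotated mixed-model scan)."""
    n = Y.shape[0]
    X = _design_tensor(G)
    Xw = np.einsum("kn,nmi->kmi", W, X)
    Yw = W @ Y
    rss1 = _marker_rss(Xw, Y=Yw)
    # null: intercept only, whitened
    ones_w = W @ np.ones((n, 1))
    denom = float((ones_w**2).sum())
    b0 = (ones_w.T @ Yw) / denom
    rss0 = (Yw**2).sum(axis=0) - denom * (b0.ravel() ** 2)
    var = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0) / n
    floor = np.maximum(RSS_FLOOR_REL * var * n, np.finfo(float).tiny)
    rss1 = np.maximum(rss1, floor[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(np.maximum(rss0[None, :], floor[None, :]) / rss1)
    return np.clip(lod, 0.0, None)


def scan(
    probs: GenotypeProbs,
    phenotype: PhenotypeVector,
    kinship=None,
) -> ScanResult:
    """Genome scan: per-marker LOD of the phenotype on founder dosages.

    The phenotype is assumed already residualized and rank-Z normalized.
    ``kinship`` may be None, a strain x strain matrix, or a {chrom: matrix}
    LOCO dict; variance components are estimated once under the null (per
    chromosome in the LOCO case).
    """
    strain_idx = _expand_units(probs, phenotype)
    G = probs.probs[strain_idx]  # (n, M, 8)
    Y = phenotype.values[:, None]
    if kinship is None:
        lod = _lod_matrix(G, Y)[:, 0]
    elif isinstance(kinship, dict):
        lod = np.empty(probs.n_markers)
        for chrom, K in kinship.items():
            cols = probs.chrom_slice(chrom)
            Ku = _expand_kinship(K, strain_idx)
            W = _whitener(Ku, _null_h2(phenotype.values, Ku))
            lod[cols] = _lod_matrix_whitened(G[:, cols, :], Y, W)[:, 0]
    else:
        Ku = _expand_kinship(np.asarray(kinship, dtype=float), strain_idx)
        W = _whitener(Ku, _null_h2(phenotype.values, Ku))
        lod = _lod_matrix_whitened(G, Y, W)[:, 0]
    df = probs.markers.copy()
    df["lod"] = lod
    return ScanResult(lod=df, n=len(phenotype.values))


# ---------------------------------------------------------------------------
# permutations


def _permuted_phenotypes(phenotype: PhenotypeVector, n_perm: int, rng) -> Optional[np.ndarray]:
    """Permuted phenotype matrix (n, n_perm) for strain-level exchange.

    Strain-level phenotypes permute directly.  Mouse-level phenotypes
    exchange whole strain blocks (mouse rows move with their strain),
    which reduces to a row permutation when strains are balanced; returns
    None for unbalanced mouse-level designs (caller falls back to
    genotype-side permutation).
    """
    vals = phenotype.values
    if phenotype.unit == "strain":
        return np.column_stack([vals[rng.permutation(vals.size)] for _ in range(n_perm)])
    strains, counts = np.unique(phenotype.strain_of, return_counts=True)
    if counts.min() != counts.max():
        return None
    r = counts[0]
    order = np.argsort(phenotype.strain_of, kind="stable")
    blocks = order.reshape(len(strains), r)
    Y = np.empty((vals.size, n_perm))
    for p in range(n_perm):
        perm = rng.permutation(len(strains))
        ycol = np.empty_like(vals)
        ycol[blocks.reshape(-1)] = vals[blocks[perm].reshape(-1)]
        Y[:, p] = ycol
    return Y


def permutation_thresholds(
    probs: GenotypeProbs,
    phenotype: PhenotypeVector,
    n_perm: int = 1000,
    alphas=DEFAULT_ALPHAS,
    seed: int = 0,
    kinship=None,
) -> dict:
    """Genome-wide LOD thresholds from strain-level phenotype permutation.

    For each permutation the genome-wide maximum LOD is recorded; the
    threshold for significance level alpha is the (1 - alpha) quantile of
    those maxima.  Mouse rows move with their strain, preserving
    within-strain replicate correlation.
    """
    for a in alphas:
        if not 0 < a < 1:
            raise ValueError(f"alpha {a} outside (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    strain_idx = _expand_units(probs, phenotype)
    G = probs.probs[strain_idx]

    if kinship is not None and not isinstance(kinship, dict):
        Ku = _expand_kinship(np.asarray(kinship, dtype=float), strain_idx)
        W = _whitener(Ku, _null_h2(phenotype.values, Ku))
        lodfun = lambda Gm, Ym: _lod_matrix_whitened(Gm, Ym, W)  # noqa: E731
    else:
        # LOCO kinship under permutation is not meaningfully pairable with
        # exchanged strains; thresholds use the unrotated model.
        lodfun = _lod_matrix

    Y = _permuted_phenotypes(phenotype, n_perm, rng)
    if Y is not None:
        maxlod = lodfun(G, Y).max(axis=0)
    else:  # unbalanced mouse-level design: permute genotype at strain level
        maxlod = np.empty(n_perm)
        uniq = list(dict.fromkeys(phenotype.strain_of))
        u_idx = {s: i for i, s in enumerate(uniq)}
        unit_u = np.array([u_idx[s] for s in phenotype.strain_of])
        strain_rows = np.array([strain_idx[phenotype.strain_of == s][0] for s in uniq])
        yv = phenotype.values[:, None]
        for p in range(n_perm):
            perm = rng.permutation(len(uniq))
            Gp = probs.probs[strain_rows[perm][unit_u]]
            maxlod[p] = lodfun(Gp, yv).max()
    return {float(a): float(np.quantile(maxlod, 1 - a)) for a in alphas}


# ---------------------------------------------------------------------------
# peaks, effects, intervals


def founder_effects(
    probs: GenotypeProbs,
    phenotype: PhenotypeVector,
    marker: str,
    kinship=None,
) -> np.ndarray:
    """Founder allele effects at a marker, sum-to-zero parameterization.

    Least-squares coefficients of the 8 dosages constrained to sum to 0
    (deviations from the population mean), fit as intercept + dosages
    through an orthonormal sum-zero basis.  If a kinship matrix is given,
    the same whitening used by the scan is applied first.
    """
    strain_idx = _expand_units(probs, phenotype)
    m = probs.marker_index(marker)
    D = probs.probs[strain_idx, m, :]  # (n, 8)
    y = phenotype.values
    Z = helmert(N_FOUNDERS).T  # (8, 7), orthonormal, columns sum to 0
    X = np.column_stack([np.ones(len(y)), D @ Z])
    if kinship is not None:
        K = kinship[probs.markers.loc[m, "chrom"]] if isinstance(kinship, dict) else kinship
        Ku = _expand_kinship(np.asarray(K, dtype=float), strain_idx)
        W = _whitener(Ku, _null_h2(y, Ku))
        X, y = W @ X, W @ y
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return Z @ coef[1:]


def credible_interval(chrom_lod: pd.DataFrame, prob: float = 0.95):
    """Bayesian credible interval for a peak on one chromosome.

    Normalizes 10^LOD over the chromosome's markers, finds the smallest
    contiguous marker interval containing the peak whose normalized mass
    is >= ``prob``, and returns the positions of the markers flanking
    that interval (clipped at the chromosome ends), in Mb.  A single
    dominant peak therefore yields its two flanking markers.
    """
    if len(chrom_lod) < 2:
        raise ValueError("credible_interval needs >= 2 markers")
    lod = chrom_lod["lod"].to_numpy(dtype=float)
    pos = chrom_lod["pos_Mb"].to_numpy(dtype=float)
    w = 10.0 ** (lod - lod.max())
    w = w / w.sum()
    if np.ptp(lod) == 0:
        warnings.warn("flat LOD profile; credible interval spans the chromosome")
        return float(pos[0]), float(pos[-1])
    peak = int(np.argmax(lod))
    best = None
    n = len(lod)
    for lo in range(peak + 1):
        cum = w[lo : peak + 1].sum()
        hi = peak
        while cum < prob and hi + 1 < n:
            hi += 1
            cum += w[hi]
        if cum >= prob:
            width = (hi - lo, pos[hi] - pos[lo])
            if best is None or width < best[0]:
                best = (width, lo, hi)
    if best is None:  # total mass < prob cannot happen (normalized); guard anyway
        return float(pos[0]), float(pos[-1])
    _, lo, hi = best
    return float(pos[max(lo - 1, 0)]), float(pos[min(hi + 1, n - 1)])


def find_peaks(
    probs: GenotypeProbs,
    result: ScanResult,
    phenotype: PhenotypeVector,
    threshold: Optional[float] = None,
    ci_prob: float = 0.95,
    kinship=None,
) -> ScanResult:
    """Annotate a scan with per-chromosome peaks, intervals, and effects.

    Keeps the maximum-LOD marker of each chromosome (all chromosomes when
    ``threshold`` is None, else only peaks at or above it).
    """
    rows = []
    effects = {}
    for chrom, grp in result.lod.groupby("chrom", sort=False):
        i = grp["lod"].idxmax()
        peak = result.lod.loc[i]
        if threshold is not None and peak["lod"] < threshold:
            continue
        if len(grp) >= 2:
            lo, hi = credible_interval(grp, ci_prob)
        else:
            lo = hi = float(peak["pos_Mb"])
        eff = founder_effects(probs, phenotype, peak["marker"], kinship=kinship)
        effects[peak["marker"]] = eff
        rows.append(
            {
                "marker": peak["marker"],
                "chrom": chrom,
                "peak_Mb": float(peak["pos_Mb"]),
                "lod": float(peak["lod"]),
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    result.peaks = pd.DataFrame(
        rows, columns=["marker", "chrom", "peak_Mb", "lod", "ci_lo", "ci_hi"]
    )
    result.effects = effects
    return result


def genotype_by_phenotype(
    probs: GenotypeProbs,
    marker: str,
    strain_phenotype: pd.Series,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Assign each strain its maximum-dosage founder(s) at a marker.

    Ties within ``tol`` report all tied founders, joined by '|'.  Joined
    with the per-strain phenotype and sorted by it, descending.
    """
    m = probs.marker_index(marker)
    rows = []
    for s_i, strain in enumerate(probs.strains):
        d = probs.probs[s_i, m, :]
        top = d.max()
        founders = [FOUNDERS[j] for j in range(N_FOUNDERS) if d[j] >= top - tol]
        rows.append(
            {
                "strain": strain,
                "founder": "|".join(founders),
                "phenotype": strain_phenotype.get(strain, np.nan),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("phenotype", ascending=False)
        .reset_index(drop=True)
    )
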