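"""Synthetic-data generators with machine-readable ground truth.

Every pipeline input can be generated here with known truth: daily score
trajectories built from disease-course archetypes, founder-mosaic genomes
with planted QTL, tissue gene networks with a planted trait module, and
variant tables with planted nonsynonymous segregating rows.  Generators
are seed-deterministic and return a truth record alongside the data so
recovery can be checked end to end.

Trajectory templates are piecewise linear in score space (ramp to peak,
hold, ramp down), the simplest family that realizes each disease-course
class exactly.  Score noise models inter-rater uncertainty: on days with
clinical disease the recorded score jitters by +/-1 with a given
probability; healthy (zero) days are unambiguous and are not perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomescan import FOUNDERS, N_FOUNDERS, GenotypeProbs, PhenotypeVector
from .prioritize import GeneNetwork
from .scores import ALIVE, DEFAULT_WINDOW, CohortTable, MouseMeta, ScoreSeries


@dataclass
class ArchetypeSpec:
    """Parameters of one disease-course trajectory archetype.

    ``remission_day`` and ``relapse_day`` are offsets in days from onset;
    only the archetypes that use them read them.
    """

    name: str
    onset_mu: float = 14.0
    onset_sd: float = 2.0
    peak: int = 3
    remission_day: int = 9  # bout length before full remission (monophasic, rr)
    relapse_day: int = 12  # days from onset to relapse bout start (rr)
    penetrance: float = 0.8
    subtype_channel: str = "classic"  # classic / ar / both

    def __post_init__(self):
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance outside [0, 1]")
        if not 1 <= self.peak <= 5:
            raise ValueError("peak outside 1-5")
        if self.subtype_channel not in ("classic", "ar", "both"):
            raise ValueError(f"bad subtype_channel {self.subtype_channel!r}")


#: Named archetypes covering the disease-course spectrum seen across CC
#: strains: near-resistance, chronic, monophasic, relapsing-remitting,
#: severe-progressive (reaching humane endpoint), and AR-dominant chronic.
ARCHETYPES = {
    "resistant": ArchetypeSpec("resistant", penetrance=0.1),
    "chronic": ArchetypeSpec("chronic", onset_mu=14, peak=3, penetrance=0.9),
    "monophasic": ArchetypeSpec("monophasic", onset_mu=13, peak=3, penetrance=0.8),
    "rr": ArchetypeSpec("rr", onset_mu=12, peak=3, penetrance=0.8),
    "progressive": ArchetypeSpec("progressive", onset_mu=10, peak=5, penetrance=0.9),
    "ar_chronic": ArchetypeSpec("ar_chronic", onset_mu=14, peak=3, penetrance=0.8,
                                subtype_channel="ar"),
}

#: Course class each incident archetype trajectory realizes (noise-free).
ARCHETYPE_COURSE = {
    "resistant": "chronic",  # the rare penetrant resistant mouse runs a chronic course
    "chronic": "chronic",
    "monophasic": "monophasic",
    "rr": "RR",
    "progressive": "chronic",  # persistent maximal disease
    "ar_chronic": "chronic",
}


def _bout(peak: int, hold: int) -> list:
    """Symmetric piecewise-linear bout: ramp up, hold, ramp down to 0."""
    return list(range(1, peak + 1)) + [peak] * hold + list(range(peak - 1, 0, -1))


def _template(spec: ArchetypeSpec, onset: int, window) -> np.ndarray:
    lo, hi = window
    n = hi - lo + 1
    arr = np.zeros(n, dtype=int)
    start = onset - lo
    name = spec.name
    if name in ("chronic", "ar_chronic", "resistant"):
        seq = list(range(1, spec.peak + 1))
        if start + len(seq) + 1 > n:
            raise ValueError(f"window too short for {name} onset {onset}")
        arr[start : start + len(seq)] = seq
        arr[start + len(seq) :] = spec.peak
    elif name == "monophasic":
        hold = max(spec.remission_day - 2 * (spec.peak - 1) - 1, 1)
        seq = _bout(spec.peak, hold)
        if start + len(seq) > n:
            raise ValueError(f"window too short for monophasic onset {onset}")
        arr[start : start + len(seq)] = seq
    elif name == "rr":
        hold1 = max(spec.remission_day - 2 * (spec.peak - 1) - 1, 1)
        bout1 = _bout(spec.peak, hold1)
        gap = spec.relapse_day - len(bout1)
        if gap < 3:
            raise ValueError("relapse_day leaves a remission shorter than 3 days")
        bout2 = _bout(spec.peak, 2)
        if start + spec.relapse_day + 2 > n:
            raise ValueError(f"window too short for rr onset {onset}")
        arr[start : start + len(bout1)] = bout1
        stop2 = min(start + spec.relapse_day + len(bout2), n)
        arr[start + spec.relapse_day : stop2] = bout2[: stop2 - start - spec.relapse_day]
    elif name == "progressive":
        seq = list(range(1, 6))
        if start + len(seq) + 3 > n:
            raise ValueError(f"window too short for progressive onset {onset}")
        arr[start : start + len(seq)] = seq
        arr[start + len(seq) :] = 5
    else:
        raise ValueError(f"unknown archetype {name!r}")
    return arr


def gen_scores(
    archetypes: dict,
    n_per_sex: int = 5,
    window=DEFAULT_WINDOW,
    noise_sd: float = 0.0,
    seed: int = 0,
    cohorts: Sequence[str] = ("C1", "C2", "C3", "C4"),
):
    """Generate a daily-score cohort from per-strain archetypes.

    ``archetypes`` maps strain label -> archetype name or ArchetypeSpec.
    Each strain gets ``n_per_sex`` mice of each sex, assigned round-robin
    to cohorts.  Incidence is Bernoulli(penetrance); incident mice follow
    their archetype template with onset ~ N(onset_mu, onset_sd) rounded,
    and disease-day scores jittered by +/-1 at rate ``noise_sd``.

    Returns (CohortTable, truth DataFrame) where truth records each
    mouse's archetype, incidence, expected course class and endpoint flag.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window
    days = np.arange(lo, hi + 1)
    n_days = days.size
    series, truth = [], []
    counter = 0
    for strain, spec in archetypes.items():
        if isinstance(spec, str):
            spec = ARCHETYPES[spec]
        for sex in ("M", "F"):
            for _ in range(n_per_sex):
                mouse_id = f"{strain}_{sex}{counter:04d}"
                cohort = cohorts[counter % len(cohorts)]
                counter += 1
                incident = rng.random() < spec.penetrance
                classic = np.zeros(n_days, dtype=int)
                ar = np.zeros(n_days, dtype=int)
                onset = None
                if incident:
                    onset = int(np.clip(round(rng.normal(spec.onset_mu, spec.onset_sd)),
                                        lo + 1, hi - 4))
                    tmpl = _template(spec, onset, window)
                    if noise_sd > 0:
                        jitter = (rng.random(n_days) < noise_sd) & (tmpl > 0)
                        step = rng.choice([-1, 1], size=n_days)
                        tmpl = np.clip(tmpl + jitter * step, 0, 5)
                    if spec.subtype_channel in ("classic", "both"):
                        classic = tmpl.copy()
                    if spec.subtype_channel in ("ar", "both"):
                        ar = tmpl.copy()
                meta = MouseMeta(mouse_id, strain, sex, cohort)
                series.append(
                    ScoreSeries(
                        mouse=meta,
                        days=days.copy(),
                        classic=classic,
                        ar=ar,
                        status=np.array([ALIVE] * n_days, dtype=object),
                    )
                )
                truth.append(
                    {
                        "mouse_id": mouse_id,
                        "strain": strain,
                        "sex": sex,
                        "cohort": cohort,
                        "archetype": spec.name,
                        "incident": incident,
                        "onset": onset,
                        "course": ARCHETYPE_COURSE[spec.name] if incident else "none",
                        "endpoint": bool(incident and spec.name == "progressive"),
                    }
                )
    return CohortTable(series=series), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# genomes and planted QTL


@dataclass
class SimGenomeSpec:
    """Founder-mosaic genome simulator settings."""

    n_strains: int = 40
    chroms: Sequence = (("1", 100, 100.0), ("2", 100, 100.0), ("3", 100, 100.0))
    switch_prob: float = 0.05  # per-marker founder-switch probability
    certainty: float = 1.0  # dosage mass on the sampled founder

    def __post_init__(self):
        if not 0 < self.switch_prob < 1:
            raise ValueError("switch_prob outside (0, 1)")
        if not 0 < self.certainty <= 1:
            raise ValueError("certainty outside (0, 1]")


def gen_genomes(spec: SimGenomeSpec, seed: int = 0) -> GenotypeProbs:
    """Founder-mosaic genomes: a Markov chain over founders per chromosome.

    The chain starts uniform over the 8 founders and switches to a
    uniformly drawn different founder with probability ``switch_prob`` at
    each marker step.  Dosages put ``certainty`` on the sampled founder
    and spread the rest evenly.
    """
    rng = np.random.default_rng(seed)
    strains = [f"CC{i + 1:03d}" for i in range(spec.n_strains)]
    marker_rows = []
    chrom_states = []
    for chrom, n_mark, length in spec.chroms:
        pos = np.linspace(0.0, float(length), n_mark)
        for j in range(n_mark):
            marker_rows.append({"marker": f"c{chrom}_m{j:04d}", "chrom": str(chrom),
                                "pos_Mb": float(pos[j])})
        states = np.empty((spec.n_strains, n_mark), dtype=int)
        states[:, 0] = rng.integers(0, N_FOUNDERS, size=spec.n_strains)
        for j in range(1, n_mark):
            switch = rng.random(spec.n_strains) < spec.switch_prob
            jump = (states[:, j - 1] + rng.integers(1, N_FOUNDERS, size=spec.n_strains)) % N_FOUNDERS
            states[:, j] = np.where(switch, jump, states[:, j - 1])
        chrom_states.append(states)
    states = np.concatenate(chrom_states, axis=1)
    off = (1.0 - spec.certainty) / (N_FOUNDERS - 1)
    probs = np.full((spec.n_strains, states.shape[1], N_FOUNDERS), off)
    s_idx, m_idx = np.meshgrid(np.arange(spec.n_strains), np.arange(states.shape[1]),
                               indexing="ij")
    probs[s_idx, m_idx, states] = spec.certainty
    return GenotypeProbs(strains, pd.DataFrame(marker_rows), probs)


@dataclass
class PlantedQTL:
    """A single planted locus with known high-effect founders."""

    marker: str
    high_founders: Sequence[str] = ("WSB", "NZO")
    beta: float = 1.0
    trait: str = "cds"  # or "incidence"
    h2_poly: float = 0.2  # polygenic fraction of the non-QTL variance
    noise_sd: float = 1.0

    def __post_init__(self):
        if not 0 <= self.h2_poly < 1:
            raise ValueError("h2_poly outside [0, 1)")
        unknown = set(self.high_founders) - set(FOUNDERS)
        if unknown:
            raise ValueError(f"unknown founders {sorted(unknown)}")


def high_dosage(probs: GenotypeProbs, marker: str, high_founders) -> np.ndarray:
    """Per-strain summed dosage of the high-effect founders at a marker."""
    m = probs.marker_index(marker)
    cols = [FOUNDERS.index(f) for f in high_founders]
    return probs.probs[:, m, cols].sum(axis=1)


def plant_qtl(probs: GenotypeProbs, planted: PlantedQTL, seed: int = 0):
    """Strain phenotypes with one planted QTL plus polygenic background.

    value = beta * (summed high-founder dosage) + polygenic + noise, where
    the polygenic term sums random founder effects over all markers,
    standardized so it contributes the fraction ``h2_poly`` of the
    non-QTL variance, and noise is iid N(0, noise_sd^2).  For
    ``trait='incidence'`` the value maps through a logistic link to a
    per-strain percentage in (0, 100).

    Returns (PhenotypeVector at strain level, truth dict).
    """
    rng = np.random.default_rng(seed)
    dose = high_dosage(probs, planted.marker, planted.high_founders)
    g = planted.beta * dose
    u = rng.normal(size=(probs.n_markers, N_FOUNDERS))
    poly = np.einsum("smf,mf->s", probs.probs, u)
    sd = poly.std()
    poly = (poly - poly.mean()) / (sd if sd > 0 else 1.0)
    s_poly = (
        planted.noise_sd * np.sqrt(planted.h2_poly / (1 - planted.h2_poly))
        if planted.h2_poly > 0
        else 0.0
    )
    value = g + s_poly * poly + rng.normal(0, planted.noise_sd, size=probs.n_strains)
    if planted.trait == "incidence":
        from scipy.special import expit

        value = 100.0 * expit(value - value.mean())
    truth = {
        "marker": planted.marker,
        "high_founders": list(planted.high_founders),
        "beta": planted.beta,
        "genetic_value": g,
    }
    phen = PhenotypeVector(values=value, strain_of=np.array(probs.strains, dtype=object),
                           unit="strain")
    return phen, truth


def expand_to_mice(
    phen: PhenotypeVector,
    n_per_strain: int = 5,
    within_sd: float = 0.5,
    seed: int = 0,
    cohorts: Optional[Sequence[str]] = ("C1", "C2", "C3", "C4"),
) -> PhenotypeVector:
    """Replicate a strain phenotype into mouse-level values with noise.

    Mirrors the study design of a handful of mice per strain: each strain
    contributes ``n_per_strain`` mice whose values are the strain value
    plus iid N(0, within_sd^2), with cohort labels assigned round-robin
    as a batch covariate.
    """
    rng = np.random.default_rng(seed)
    vals, strain_of, coh = [], [], []
    i = 0
    for s, v in zip(phen.strain_of, phen.values):
        for _ in range(n_per_strain):
            vals.append(v + rng.normal(0, within_sd))
            strain_of.append(s)
            if cohorts:
                coh.append(cohorts[i % len(cohorts)])
            i += 1
    cov = pd.DataFrame({"cohort": coh}) if cohorts else None
    return PhenotypeVector(values=np.array(vals), strain_of=np.array(strain_of, dtype=object),
                           unit="mouse", covariates=cov)


# ---------------------------------------------------------------------------
# networks


def gen_network(
    n_genes: int = 2000,
    module_size: int = 150,
    w_in_mean: float = 1.0,
    w_bg_mean: float = 0.2,
    density: float = 0.05,
    seed: int = 0,
    n_positives: int = 100,
    n_background_candidates: Optional[int] = None,
):
    """Random weighted network with a planted trait module.

    Every gene pair carries an edge with probability ``density``; edge
    weights are exponential with mean ``w_in_mean`` when both endpoints
    lie in the planted module and ``w_bg_mean`` otherwise.  Positives are
    sampled from the module; the held-out module genes are the planted
    true candidates, matched by an equal-size background candidate draw.

    Returns (GeneNetwork, truth dict) with keys module, positives,
    candidates_planted, candidates_background, negative_pool.
    """
    if module_size >= n_genes:
        raise ValueError("module_size must be < n_genes")
    if n_positives >= module_size:
        raise ValueError("n_positives must be < module_size (to hold candidates out)")
    if w_in_mean <= w_bg_mean:
        import warnings

        warnings.warn("w_in_mean <= w_bg_mean: planted module carries no signal")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    module = set(rng.choice(n_genes, size=module_size, replace=False).tolist())
    iu, ju = np.triu_indices(n_genes, k=1)
    keep = rng.random(iu.size) < density
    iu, ju = iu[keep], ju[keep]
    in_mod = np.fromiter((i in module for i in iu), bool, iu.size) & np.fromiter(
        (j in module for j in ju), bool, ju.size
    )
    w = rng.exponential(scale=w_bg_mean, size=iu.size)
    w[in_mod] = rng.exponential(scale=w_in_mean, size=int(in_mod.sum()))
    net = GeneNetwork.from_edges(zip(genes[iu], genes[ju], w))
    mod_list = [genes[i] for i in sorted(module)]
    perm = rng.permutation(len(mod_list))
    positives = [mod_list[i] for i in perm[:n_positives]]
    planted_cands = [mod_list[i] for i in perm[n_positives:]]
    background = [g for i, g in enumerate(genes) if i not in module]
    nbc = n_background_candidates if n_background_candidates is not None else len(planted_cands)
    bg_perm = rng.permutation(len(background))
    bg_cands = [background[i] for i in bg_perm[:nbc]]
    neg_pool = [background[i] for i in bg_perm[nbc:]]
    truth = {
        "module": mod_list,
        "positives": positives,
        "candidates_planted": planted_cands,
        "candidates_background": bg_cands,
        "negative_pool": neg_pool,
    }
    return net, truth


# ---------------------------------------------------------------------------
# variants


def gen_variants(
    interval,
    genes: Sequence[str],
    n_rows: int = 200,
    frac_missense: float = 0.3,
    frac_segregating: float = 0.4,
    founders=("WSB", "NOD"),
    seed: int = 0,
    frac_outside: float = 0.2,
):
    """Variant table with a known count of qualifying nonsynonymous rows.

    Each row gets a position (a fraction ``frac_outside`` land outside
    the interval), a gene from ``genes``, a consequence (missense with
    probability ``frac_missense``, else synonymous), and per-founder
    alleles where the first named founder differs from the second with
    probability ``frac_segregating``.

    Returns (DataFrame, n_qualifying) where n_qualifying counts rows that
    are simultaneously in-interval, missense, and segregating between the
    two named founders.
    """
    chrom, lo, hi = interval
    fa, fb = founders
    rng = np.random.default_rng(seed)
    rows = []
    n_qualifying = 0
    span = hi - lo
    for i in range(n_rows):
        outside = rng.random() < frac_outside
        if outside:
            pos = hi + 0.001 + rng.random() * max(span, 1.0)
        else:
            pos = lo + rng.random() * span
        missense = rng.random() < frac_missense
        segregating = rng.random() < frac_segregating
        ref, alt = "A", "G"
        alleles = {f: ref for f in FOUNDERS}
        if segregating:
            alleles[fa] = alt
        if (not outside) and missense and segregating:
            n_qualifying += 1
        rows.append(
            {
                "chrom": str(chrom),
                "pos_Mb": pos,
                "gene": genes[int(rng.integers(0, len(genes)))],
                "consequence": "missense_variant" if missense else "synonymous_variant",
                **alleles,
            }
        )
    return pd.DataFrame(rows), n_qualifying
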