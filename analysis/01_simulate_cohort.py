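#!/usr/bin/env python
"""Simulate the full synthetic study bundle.

Generates founder-mosaic genomes for 32 strains, plants an EAE-incidence
QTL (WSB/NZO high, NOD low) on chromosome 2, converts the planted
per-strain incidence into archetype penetrances so the daily-score
cohort is genetically coupled to the genomes, and writes scores,
genotype probabilities, a two-tissue gene network with a planted trait
module, and a variant table — all with truth sidecars — under
results/sim/.
"""

import json
from pathlib import Path

import numpy as np

from eaemap import scores as sc
from eaemap import simulate as sim

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20260924
QTL_MARKER = "c2_m0050"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # genomes: 32 strains, 3 chromosomes x 100 markers
    probs = sim.gen_genomes(sim.SimGenomeSpec(n_strains=32), seed=SEED)
    probs.write(OUT / "probs.tsv")

    # planted incidence QTL drives per-strain penetrance
    pq = sim.PlantedQTL(marker=QTL_MARKER, high_founders=("WSB", "NZO"),
                        beta=3.5, trait="incidence", h2_poly=0.1, noise_sd=0.3)
    phen, truth_qtl = sim.plant_qtl(probs, pq, seed=SEED + 1)
    penetrance = phen.values / 100.0

    # disease archetypes whose penetrance follows the planted QTL;
    # course archetype varies across strains for phenotypic diversity
    courses = ["ar_chronic", "chronic", "monophasic", "rr"]
    archetypes = {}
    for i, strain in enumerate(probs.strains):
        base = sim.ARCHETYPES[courses[int(rng.integers(0, len(courses)))]]
        archetypes[strain] = sim.ArchetypeSpec(
            base.name, base.onset_mu, base.onset_sd, base.peak,
            base.remission_day, base.relapse_day,
            penetrance=float(penetrance[i]),
            subtype_channel="ar" if rng.random() < 0.5 else "classic",
        )
    table, truth_scores = sim.gen_scores(archetypes, n_per_sex=5,
                                         noise_sd=0.1, seed=SEED + 2)
    sc.write_scores(table, OUT / "scores.tsv")
    truth_scores.to_csv(OUT / "scores.truth.tsv", sep="\t", index=False)

    # gene networks with a planted trait module (immune + cns tissues)
    for tissue, seed in (("immune", SEED + 3), ("cns", SEED + 4)):
        net, truth_net = sim.gen_network(
            n_genes=2000, module_size=150, n_positives=100,
            w_in_mean=1.0, w_bg_mean=0.05, density=0.15, seed=seed,
        )
        net.tissue = tissue
        net.write(OUT / f"network_{tissue}.tsv")
        (OUT / f"network_{tissue}.truth.json").write_text(json.dumps(truth_net))
        if tissue == "immune":
            (OUT / "positives.txt").write_text("\n".join(truth_net["positives"]))
            cands = (truth_net["candidates_planted"][:20]
                     + truth_net["candidates_background"][:20])
            (OUT / "candidates.txt").write_text("\n".join(cands))

    # variant table around the planted locus
    variants, n_qual = sim.gen_variants(
        ("2", 45.0, 56.0), [f"Gene{k}" for k in range(12)], n_rows=200,
        frac_missense=0.3, frac_segregating=0.4, founders=("WSB", "NOD"),
        seed=SEED + 5,
    )
    variants.to_csv(OUT / "variants.tsv", sep="\t", index=False)

    truth = {
        "seed": SEED,
        "qtl_marker": QTL_MARKER,
        "high_founders": ["WSB", "NZO"],
        "planted_incidence_pct": dict(zip(probs.strains, phen.values.round(2))),
        "n_qualifying_variants": n_qual,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))
    print(f"wrote synthetic bundle to {OUT}")
    print(f"  {len(table)} mice across {probs.n_strains} strains, "
          f"{probs.n_markers} markers")
    print(f"  planted incidence QTL at {QTL_MARKER} "
          f"(incidence range {phen.values.min():.0f}-{phen.values.max():.0f}%)")
    print(f"  {n_qual} qualifying nsSNPs planted in the variant table")


if __name__ == "__main__":
    main()
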