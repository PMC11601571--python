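#!/usr/bin/env python
"""Derive per-mouse trait variables and per-strain summaries.

Reads the simulated daily scores, applies the humane-endpoint and
mortality rules, derives cumulative disease scores, incidence, subtype,
and disease course per mouse, and writes the per-strain summary table
used for mapping.
"""

from pathlib import Path


from eaemap import qtv
from eaemap import scores as sc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = sc.apply_endpoint_rules(sc.read_scores(ROOT / "sim" / "scores.tsv"))
    df = qtv.derive_qtv(table)
    df.to_csv(ROOT / "qtv.tsv", sep="\t", index=False)
    summary = qtv.summarize_strain(df)
    summary.to_csv(ROOT / "strain_summary.tsv", sep="\t", index=False)
    by_sex = qtv.summarize_strain(df, by=["strain", "sex"])
    by_sex.to_csv(ROOT / "strain_summary_by_sex.tsv", sep="\t", index=False)

    print(f"{len(df)} mice kept, {len(table.excluded)} excluded")
    print(f"overall incidence {df['eae_incident'].mean() * 100:.0f}%; "
          f"course mix: {df[df['eae_incident']]['course'].value_counts().to_dict()}")
    top = summary.sort_values("ar_incidence_pct", ascending=False).head(5)
    print("top 5 strains by AR incidence:")
    print(top[["strain", "ar_incidence_pct", "mean_cds"]].to_string(index=False))


if __name__ == "__main__":
    main()
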