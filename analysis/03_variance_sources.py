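#!/usr/bin/env python
"""Identify the sources of variation in the uncorrected data.

PCA of the log2 matrix, a joint five-factor ANOVA per protein (IGHV
status, WBC class, gender, preparation day, MS run; 10% BH-FDR), and
partial correlation with the continuous %-IGHV covariate (WBC and gender
as confounders).  The expected picture: samples cluster by preparation
day on the first components, the prep-day factor dominates the
significant counts, and the MS-run factor is near-null.

Writes per-factor tables, PCA scores and an overlap report under
results/variance/.
"""

import json
from pathlib import Path

from proteopower import diffstats, prep
from proteopower.diffstats import DesignSpec, retention_and_overlap

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "study"
OUT = ROOT / "variance"


def main() -> None:
    log2m = prep.read_matrix(STUDY / "matrix_log2.tsv", scale="log2")
    metadata = prep.read_metadata(STUDY / "metadata.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    pca_res = diffstats.pca(log2m)
    pca_res.scores.iloc[:, :5].to_csv(OUT / "pca_scores.tsv", sep="\t")
    frac = pca_res.fraction_explained
    print(f"PCA: PC1 {100 * frac[0]:.1f}%, PC2 {100 * frac[1]:.1f}% of variance")
    # does PC1 separate preparation days?
    days = metadata.aligned_to(log2m.sample_ids).table["prep_day"]
    by_day = pca_res.scores.iloc[:, 0].groupby(days.to_numpy()).mean()
    print(f"PC1 mean score per prep day: {by_day.round(1).to_dict()}")

    res = diffstats.anova_per_protein(log2m, metadata, DesignSpec())
    print("\nANOVA significant proteins (10% FDR):")
    for factor, r in res.items():
        r.table.to_csv(OUT / f"anova_{factor}.tsv", sep="\t")
        print(f"  {factor:12s} {r.n_significant:5d}")

    pcorr = diffstats.partial_correlation(log2m, metadata)
    pcorr.table.to_csv(OUT / "partial_correlation_ighv_percent.tsv", sep="\t")
    print(f"  %-IGHV partial correlation: {pcorr.n_significant} significant")

    overlap = retention_and_overlap(
        res["ighv_status"].significant_ids,
        pcorr.significant_ids,
        names=("anova_ighv", "partial_corr"),
    )
    (OUT / "ighv_overlap.json").write_text(json.dumps(
        {"venn_counts": {"&".join(k): v for k, v in overlap["venn_counts"].items()},
         "intersection": overlap["intersection"]}, indent=1))
    print(f"\nANOVA-IGHV ∩ partial-correlation: {overlap['intersection']} proteins")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
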