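#!/usr/bin/env python
"""Abundance-dependent error model and proteome-wide power analysis.

Per-protein CVs are computed on the batch-corrected intensities
(back-transformed to the raw scale) treating all 54 acquisitions as
biological replicates; a loess curve of CV versus log2 mean abundance is
fitted; and CVs are propagated into two-sided two-sample t-test power
for a two-fold change at a Bonferroni-corrected family alpha of 0.1.
Outputs the fitted curve, the power-vs-abundance surface per group size,
the required-n-per-subgroup curve at 90% power, and the coverage table
(percent of the proteome reaching 95/75/50% power per group size).

Writes tables and figures under results/power/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from proteopower import powermodel, prep

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "power"


def main() -> None:
    corrected = prep.read_matrix(ROOT / "batchfix" / "matrix_combat_s.tsv",
                                 scale="log2")
    raw_back = corrected.copy_with(np.power(2.0, corrected.values), scale="raw")
    OUT.mkdir(parents=True, exist_ok=True)

    stats_ = powermodel.protein_stats(raw_back)
    model = powermodel.fit_error_model(stats_, span=0.75)
    model.to_frame().to_csv(OUT / "error_model.tsv", sep="\t", index=False)
    print(f"fitted CV curve over {stats_.table.shape[0]} proteins: "
          f"{model.grid_cv[-1]:.1f}% (high abundance) to "
          f"{model.grid_cv[0]:.1f}% (low abundance)")

    spec = powermodel.PowerSpec(n_tests=raw_back.n_proteins)
    surface = powermodel.power_surface(model, spec)
    surface.to_csv(OUT / "power_surface.tsv", sep="\t")

    sigmas = powermodel.protein_sigmas(stats_, model, smoothed=True)
    table = powermodel.coverage_table(sigmas, spec)
    table.to_csv(OUT / "coverage_table.tsv", sep="\t")
    print("\ncoverage table (% of proteins meeting each power target):")
    print(table.to_string())

    # required n per subgroup at 90% power across the abundance range
    grid_sigma = powermodel.cv_to_sigma_log2(model.grid_cv)
    req = np.array([
        powermodel.required_n(s, 0.9, spec.log2_fc, spec.alpha_per_test)
        for s in grid_sigma
    ], dtype=float)
    req[req < 0] = np.nan
    np.savetxt(OUT / "required_n_90pct.tsv",
               np.column_stack([model.grid_log2, req]),
               delimiter="\t", header="mean_log2\tn_required", comments="")

    fig, axes = plt.subplots(1, 3, figsize=(15, 4))
    axes[0].scatter(stats_.mean_log2, stats_.cv_percent, s=3, alpha=0.3)
    axes[0].plot(model.grid_log2, model.grid_cv, color="crimson", lw=2)
    axes[0].set(xlabel="log2 mean abundance", ylabel="CV (%)",
                title="error model (loess)")
    for n in spec.n_per_group_grid:
        axes[1].plot(surface.index, 100 * surface[n], label=f"n={n}")
    axes[1].set(xlabel="log2 mean abundance", ylabel="power (%)",
                title="power vs abundance (2-fold, Bonferroni 0.1)")
    axes[1].legend(fontsize=7)
    axes[2].plot(model.grid_log2, req)
    axes[2].set(xlabel="log2 mean abundance", ylabel="n per subgroup",
                title="required n at 90% power")
    fig.tight_layout()
    fig.savefig(OUT / "power_analysis.png", dpi=120)
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
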