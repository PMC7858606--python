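#!/usr/bin/env python
"""Generate the synthetic SWATH-MS study that the downstream analyses use.

Emulates the 6-patient (3 UM-CLL + 3 M-CLL) x 3-preparation-day x 3-MS-run
design: 54 acquisitions over 1200 proteins with abundance-dependent CV,
additive prep-day batch offsets, per-preparation block noise, 10% of
proteins differentially expressed two-fold between IGHV groups, and mild
abundance-dependent missingness.

Writes results/study/{matrix_raw.tsv, metadata.tsv, ground_truth.json}.
"""

from pathlib import Path

from proteopower import prep
from proteopower.synthdata import SyntheticConfig, generate_study

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = SyntheticConfig(n_proteins=1200, seed=SEED)
    matrix, metadata, truth = generate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    prep.write_matrix(matrix, OUT / "matrix_raw.tsv")
    prep.write_metadata(metadata, OUT / "metadata.tsv")
    truth.to_json(OUT / "ground_truth.json")

    n_missing = int(matrix.values.isna().to_numpy().sum())
    print(f"study: {matrix.n_proteins} proteins x {matrix.n_samples} acquisitions")
    print(f"patients: {metadata.table['patient_id'].nunique()} "
          f"({(metadata.table.groupby('patient_id').first()['ighv_status'] == 'UM').sum()} UM)")
    print(f"injected DE proteins: {len(truth.de_protein_ids)} at "
          f"{truth.true_log2fc.abs().max():.1f} log2 fold change")
    print(f"missing cells: {n_missing} "
          f"({100 * n_missing / matrix.values.size:.2f}%)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
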