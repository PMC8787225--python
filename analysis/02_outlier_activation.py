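"""Call per-subtype outlier activation of the focal TF.

Reads the cohort from results/data/, computes FPKM (in-matrix library
sizes), applies the expressed-gene filter, flags samples above the
subtype mean + 3·SD of the focal TF's FPKM, and partitions the cohort
into outlier / normal / excluded groups.  Writes outlier_calls.tsv and
groups.tsv under results/ and prints the outlier percentage in the
report's two-decimal convention.
"""

import argparse
from pathlib import Path

import tfact
from tfact import io
from tfact.outliers import outlier_calls_frame
from tfact.pipeline import format_percent

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=REPO / "results" / "data")
    ap.add_argument("--out", type=Path, default=REPO / "results")
    ap.add_argument("--tf", default="GENE_TF")
    args = ap.parse_args()

    counts, samples, models = io.read_counts(
        args.data / "counts.tsv", args.data / "samples.tsv", args.data / "gene_models.tsv"
    )
    fpkm = tfact.compute_fpkm(counts, models)
    expressed = tfact.filter_expressed(fpkm, io.gene_models_frame(models)["biotype"])
    row = fpkm.fpkm.loc[args.tf]
    calls = tfact.call_subtype_outliers(row, samples, gene_id=args.tf)
    groups = tfact.assign_groups(calls, samples)

    args.out.mkdir(parents=True, exist_ok=True)
    outlier_calls_frame(calls).to_csv(args.out / "outlier_calls.tsv", sep="\t", index=False)
    groups.rename_axis("sample_id").reset_index().to_csv(
        args.out / "groups.tsv", sep="\t", index=False
    )

    n_out = int((groups == "outlier").sum())
    print(f"expressed genes: {len(expressed)} of {counts.shape[0]}")
    print(f"focal TF background median FPKM: {row[groups != 'outlier'].median():.3f}")
    for c in calls:
        if c.outlier_samples:
            print(f"  {c.subtype}: n={c.n_samples} threshold={c.threshold:.2f} "
                  f"outliers={len(c.outlier_samples)}")
    print(f"outliers: {n_out} of {len(samples)} subtype-annotated samples "
          f"({format_percent(n_out, len(samples))}%)")


if __name__ == "__main__":
    main()
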