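"""Generate the synthetic B-ALL-style cohort and write every pipeline input.

Writes counts, sample sheet, gene models, genome FASTA, PWM, ChIP-like
peaks, allele counts, CNV segments, TADs, marker panels and the ground
truth to results/data/.  Defaults mirror the printed cohort bookkeeping:
629 subtype-annotated samples, 13 planted outliers in 7 subtypes,
33 up / 13 down planted targets, 313 motif promoters.
"""

import argparse
from pathlib import Path

import tfact
from tfact import simulate

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--preset", choices=["default", "small"], default="default")
    ap.add_argument("--out", type=Path, default=REPO / "results" / "data")
    args = ap.parse_args()

    cfg = (
        tfact.SimConfig.small(args.seed)
        if args.preset == "small"
        else tfact.SimConfig(seed=args.seed)
    )
    counts, samples, models, truth = tfact.simulate_cohort(cfg)
    genome, pwm, peaks = tfact.simulate_regulome(cfg, models, truth)
    allele, cnv, tads = tfact.simulate_cis_case(cfg, models, truth)
    panels = simulate.default_marker_panels(truth)
    paths = simulate.write_inputs(
        args.out, counts, samples, models, truth,
        genome=genome, pwm=pwm, peaks=peaks,
        allele_counts=allele, cnv=cnv, tads=tads, panels=panels,
    )
    print(f"cohort: {counts.shape[0]} genes x {counts.shape[1]} samples "
          f"({len(cfg.subtype_sizes)} subtypes)")
    print(f"planted: {len(truth.outlier_samples)} outlier samples, "
          f"{len(truth.up_targets)} up / {len(truth.down_targets)} down targets, "
          f"{len(truth.motif_genes)} motif promoters")
    print(f"wrote {len(paths)} files under {args.out}")


if __name__ == "__main__":
    main()
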