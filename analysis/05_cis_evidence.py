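"""Cis-activation evidence for the focal TF in its top outlier sample.

Tests allele-specific expression at heterozygous markers, classifies the
copy-number segment, checks whether it disrupts a TAD boundary near the
TF, and combines the three evidence lines into a verdict.  Writes
cis_report.json under results/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from tfact import cis, io

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=REPO / "results" / "data")
    ap.add_argument("--out", type=Path, default=REPO / "results")
    ap.add_argument("--tf", default="GENE_TF")
    args = ap.parse_args()

    models = {m.gene_id: m for m in io.read_gene_models(args.data / "gene_models.tsv")}
    gene = models[args.tf]
    allele = io.read_allele_counts(args.data / "allele_counts.tsv")
    seg_df = io.read_seg(args.data / "cnv.seg")
    tads = io.read_bed(args.data / "tads.bed")
    groups = pd.read_csv(args.out / "groups.tsv", sep="\t", index_col=0)["group"]
    sample = sorted(groups.index[groups == "outlier"])[0]

    ase = cis.ase_test(allele)[args.tf]
    print(f"ASE: {ase.gene_call} ({len(ase.markers)} covered markers, "
          f"direction {ase.direction})")

    segs = [
        cis.CnvSegment(str(r.chrom), int(r.start), int(r.end), float(r.log2_ratio),
                       None if pd.isna(r.loh_segment_mean) else float(r.loh_segment_mean))
        for r in seg_df.itertuples(index=False)
    ]
    deletion = min((s for s in segs if s.chrom == gene.chrom), key=lambda s: s.log2_ratio)
    call = cis.classify_deletion(deletion)
    print(f"deletion: {call.classification} ({deletion.length / 1000:.0f} kb, "
          f"log2 ratio {deletion.log2_ratio}, LOH-supported: {call.loh_supported})")

    disruption = cis.boundary_disruption(deletion, tads, gene)
    print(f"TAD boundary disrupted: {disruption[0]} "
          f"(deletion starts {disruption[1] / 1000:.0f} kb from the TSS)")

    report = cis.integrate_cis(args.tf, sample, True, ase, deletion, call, disruption)
    with open(args.out / "cis_report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=1, default=str)
    print(f"verdict for {sample}: {report.verdict}")


if __name__ == "__main__":
    main()
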