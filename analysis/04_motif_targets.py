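"""Promoter motif scanning and direct-target nomination.

Profiles peak-to-TSS distances (justifying the TSS ±100 bp scan window),
scans every protein-coding promoter with the PWM at exact p < 1e-4, and
nominates targets as motif-positive DEGs annotated with the TF
co-expression (Pearson on log2(FPKM+1)).  Writes motif_hits.tsv and
candidates.tsv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

import tfact
from tfact import io, motif
from tfact.diffexp import DEGSets
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
    coding = [m for m in models if m.biotype == "protein_coding"]
    genome = io.read_fasta(args.data / "genome.fa")
    pwm = motif.Pwm.from_meme(args.data / "motif.meme")
    peaks = io.read_bed(args.data / "peaks.bed")

    profile = motif.peak_tss_profile(peaks, coding)
    print(f"peaks with a TSS within 2 kb: {profile.n_within_near}; "
          f"within ±100 bp: {profile.n_within_core} "
          f"({format_percent(profile.n_within_core, profile.n_within_near, 1)}%)")

    promoters = motif.extract_promoters(coding, genome)
    hits = motif.best_hits(promoters, pwm)
    print(f"motif-positive promoters at p < 1e-4: {len(hits)} of {len(promoters)}")

    degs_df = pd.read_csv(args.out / "degs.tsv", sep="\t")
    degs = DEGSets(
        up=set(degs_df.loc[degs_df.direction == "up", "gene_id"]),
        down=set(degs_df.loc[degs_df.direction == "down", "gene_id"]),
    )
    de = pd.read_csv(args.out / "de_results.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(args.out / "groups.tsv", sep="\t", index_col=0)["group"]
    in_scope = list(groups.index[groups != "excluded"])
    fpkm = tfact.compute_fpkm(counts, models)
    cands = motif.nominate_targets(hits, degs, fpkm.fpkm, args.tf, in_scope,
                                   de_pvalues=de["p_value"])
    pd.DataFrame(
        [(c.gene_id, c.deg_direction, c.pearson_r, c.pearson_p, c.de_p) for c in cands],
        columns=["gene_id", "direction", "pearson_r", "pearson_p", "de_p"],
    ).to_csv(args.out / "candidates.tsv", sep="\t", index=False)
    n_up = sum(c.deg_direction == "up" for c in cands)
    print(f"nominated targets: {len(cands)} ({n_up} up, {len(cands) - n_up} down)")
    for c in cands[:5]:
        print(f"  {c.gene_id}: {c.deg_direction}, r = {c.pearson_r:.2f} "
              f"(p = {c.pearson_p:.1e}), DE p = {c.de_p:.1e}")


if __name__ == "__main__":
    main()
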