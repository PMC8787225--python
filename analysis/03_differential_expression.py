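"""Differential expression between the outlier and normal groups.

Fits the subtype-adjusted NB GLM to every expressed gene, calls DEGs at
|fold change| > 1.5 and p < 0.05, and tests the clinical-style marker
panels for enrichment in each DEG direction (Fisher's exact test).
Writes de_results.tsv, degs.tsv under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import tfact
from tfact import diffexp, io

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=REPO / "results" / "data")
    ap.add_argument("--out", type=Path, default=REPO / "results")
    args = ap.parse_args()

    counts, samples, models = io.read_counts(
        args.data / "counts.tsv", args.data / "samples.tsv", args.data / "gene_models.tsv"
    )
    fpkm = tfact.compute_fpkm(counts, models)
    expressed = tfact.filter_expressed(fpkm, io.gene_models_frame(models)["biotype"])
    groups = pd.read_csv(args.out / "groups.tsv", sep="\t", index_col=0)["group"]

    offsets = pd.Series(np.log(fpkm.library_sizes.to_numpy(float)),
                        index=fpkm.library_sizes.index)
    de = diffexp.fit_nb_glm_many(
        counts.loc[sorted(expressed)], samples, groups,
        offsets=offsets, covariates=("subtype", "batch"),
    )
    degs = diffexp.call_degs(de)
    de.rename_axis("gene_id").reset_index().to_csv(
        args.out / "de_results.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(g, "up") for g in sorted(degs.up)] + [(g, "down") for g in sorted(degs.down)],
        columns=["gene_id", "direction"],
    ).to_csv(args.out / "degs.tsv", sep="\t", index=False)
    print(f"tested {len(de)} expressed genes; "
          f"{len(degs.up)} up + {len(degs.down)} down = "
          f"{len(degs.up) + len(degs.down)} DEGs")

    panels_path = args.data / "panels.gmt"
    if panels_path.exists():
        for name, members in io.read_gmt(panels_path).items():
            panel = diffexp.MarkerPanel(name, members)
            for direction in ("up", "down"):
                res = diffexp.marker_enrichment(degs, panel, expressed, direction)
                a = res.table[0, 0]
                print(f"  panel {name} ({direction}): {a} of {len(members)} markers, "
                      f"one-sided p = {res.p_one_sided:.2e}")


if __name__ == "__main__":
    main()
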