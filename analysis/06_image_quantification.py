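"""Quantify synthetic nucleus images: integrated intensity and focus texture.

Simulates 50 control/mutant nucleus pairs carrying a 2.2-fold integrated
nuclear-intensity difference (the scale of the strongest repressive-mark
change seen at the two-cell stage), recovers the fold change from the masked
images, and compares gray-level co-occurrence entropy between groups with a
normality-gated t-test.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, images_config

from mztkit.images import (
    NucleusImage,
    compare_groups,
    compute_glcm,
    group_fold_change,
    haralick_features,
    integrated_intensity,
)
from mztkit.sim import simulate_nucleus_images


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = images_config()
    nuclei = simulate_nucleus_images(cfg)
    rows = []
    for nuc in nuclei:
        image = NucleusImage(nuc.image, nuc.mask, nuc.metadata)
        vals = nuc.image[nuc.mask]
        row = {
            "nucleus": nuc.metadata["embryo_id"],
            "genotype": nuc.genotype,
            "integrated_intensity": integrated_intensity(image),
            "mean_intensity": float(vals.mean()),
            "max_intensity": float(vals.max()),
        }
        row.update(haralick_features(compute_glcm(image)))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("nucleus")
    df.to_csv(RESULTS / "nucleus_stats.tsv", sep="\t")

    mut = df[df["genotype"] == "mutant"]
    ctrl = df[df["genotype"] == "control"]
    ratio, p = group_fold_change(mut["integrated_intensity"], ctrl["integrated_intensity"])
    print(f"planted intensity ratio {cfg.mutant_intensity_ratio}; recovered "
          f"{ratio:.3f} from {cfg.n_nuclei} pairs (t-test p = {p:.2e})")

    ent = compare_groups(mut["entropy"], ctrl["entropy"])
    flag = "" if ent.normality_ok else " [normality flag raised]"
    print(f"GLCM entropy mutant vs control: t = {ent.t_statistic:.2f}, "
          f"p = {ent.p_value:.2e}{flag}")
    print("wrote results/nucleus_stats.tsv (per-nucleus intensity + texture)")


if __name__ == "__main__":
    main()
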