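"""Compute microstructural integrity indices for the simulated cohort.

Reads the cohort written by 01_simulate_cohort.py, restricts the skeleton
to voxels with mean control FA >= 0.2, z-scores every patient against the
control distribution, and writes the per-patient global MII plus the
lesion / NAWM regional summaries (percent of control and mean z).
"""

from pathlib import Path

from mspls import io, mii

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT = BASE / "cohort"
OUT = BASE / "mii"


def main() -> None:
    paths = {
        p.stem.split("_", 1)[1]: p for p in sorted((COHORT / "skeleton").glob("*.tsv"))
    }
    cohort = io.read_skeleton_tsv(paths)
    masks, _ = io.read_masks_tsv(COHORT / "lesion_masks.tsv")
    masks = mii.binarize_lesion_mask(masks)

    keep = mii.select_skeleton_voxels(cohort.controls("fa").mean(axis=0))
    print(f"skeleton: {keep.size}/{cohort.n_voxels} voxels kept at mean FA >= 0.2")
    cohort, masks = cohort.restrict(keep), masks[:, keep]

    stats = {m: mii.control_voxel_stats(cohort, m) for m in cohort.metrics}
    summary = mii.regional_summary(cohort, stats, masks)
    glob = mii.global_mii_table(cohort, stats)

    OUT.mkdir(parents=True, exist_ok=True)
    summary.to_csv(OUT / "regional_summary.tsv", sep="\t", index=False,
                   float_format=io.FLOAT_FMT)
    glob.to_csv(OUT / "global_mii.tsv", sep="\t", index=False,
                float_format=io.FLOAT_FMT)

    wide = summary.pivot_table(index="metric", columns="region",
                               values="percent_of_control")
    print("mean percent-of-control by metric and region:")
    print(wide.round(2).to_string())
    print("mean global MII by metric:")
    print(glob.groupby("metric")["global_mii"].mean().round(3).to_string())


if __name__ == "__main__":
    main()
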