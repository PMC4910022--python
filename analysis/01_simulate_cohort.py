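"""Simulate the study-style cohort and write its data products.

Generates 30 tumours (three prognostic subgroups of 10) with five aligned
marker grids each — irregular ~75-square sections with outermost-layer
marker enrichment — plus an 8-patient centre/periphery variant cohort.
Writes grid TSVs, example heat maps, and the variant files under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

from ith_niche.grid_quant import heatmap_export
from ith_niche.grids import write_grid_tsv
from ith_niche.simulate_grids import GridSimConfig, simulate_cohort
from ith_niche.simulate_variants import VariantSimConfig, simulate_variant_tables

COHORT_SEED = 2016
VARIANT_SEED = 613
RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_cohort():
    """The deterministic simulated cohort shared by all analysis scripts."""
    return simulate_cohort(n_per_subgroup=10, base_cfg=GridSimConfig(), seed=COHORT_SEED)


def main() -> None:
    cohort_dir = RESULTS / "cohort"
    cohort = load_cohort()
    n_squares = 0
    for panel, truth in cohort:
        tdir = cohort_dir / panel.tumour_id
        tdir.mkdir(parents=True, exist_ok=True)
        for marker, grid in panel.grids.items():
            write_grid_tsv(grid, tdir / f"{marker}.tsv")
            n_squares += len(grid.analysed_values())
    print(f"wrote {len(cohort)} tumours x 5 markers to {cohort_dir}")
    print(f"total data points (squares x markers): {n_squares}")

    maps_dir = RESULTS / "heatmaps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    panel, _ = cohort[0]
    for marker, grid in panel.grids.items():
        scale = 100.0 if marker in ("HIF1A", "HIF2A") else 25.0
        heatmap_export(grid, out_png=str(maps_dir / f"{panel.tumour_id}_{marker}.png"), scale_max=scale)
    print(f"wrote example heat maps for {panel.tumour_id} to {maps_dir}")

    var_dir = RESULTS / "variants"
    res = simulate_variant_tables(VariantSimConfig(seed=VARIANT_SEED), var_dir)
    print(
        f"wrote {len(res.truth)} variants ({res.config.n_patients} patients, "
        f"central/peripheral call sets) to {var_dir}"
    )


if __name__ == "__main__":
    main()
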