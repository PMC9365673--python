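"""End-to-end convenience pipelines over the synthetic generators.

These compose generation and measurement exactly the way a user would at
the shell: render fields of planted droplets, run the full morphometry
pipeline (projection, thresholding, watershed, ellipse fit, filters) and
pool the results.  They are what the validation entry points run.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .morphometry import count_lds_per_cell, measure_stack, passing_diameters
from .synthetic.imaging import ImagingPlant, generate_ld_image_stack


def measure_planted_population(diameter_law: Tuple,
                               n_droplets: int,
                               seed: int,
                               droplets_per_field: int = 30,
                               field_shape: Tuple[int, int] = (256, 256),
                               cfg: Optional[AnalysisConfig] = None,
                               **plant_overrides
                               ) -> Dict[str, np.ndarray]:
    """Plant >= `n_droplets` droplets across fields and measure them all.

    Returns the planted true diameters and the measured (passing) major-axis
    diameters, pooled over fields.
    """
    cfg = cfg or AnalysisConfig()
    plant = ImagingPlant(diameter_law=diameter_law,
                         droplets_per_field=droplets_per_field,
                         field_shape=field_shape, **plant_overrides)
    true_d = []
    measured = []
    field = 0
    while len(true_d) < n_droplets:
        stack, _mask, gt = generate_ld_image_stack(
            plant, seed=seed + field)
        _labels, table = measure_stack(stack, plant.pixel_size_um, cfg)
        true_d.extend(gt.droplets["diameter_um"].tolist())
        measured.extend(passing_diameters(table).tolist())
        field += 1
    return {"true": np.asarray(true_d),
            "measured": np.asarray(measured),
            "n_fields": field}


def measure_cell_population(count_law: Tuple,
                            n_cells: int,
                            diameter_law: Tuple,
                            seed: int,
                            cells_per_field: int = 12,
                            field_shape: Tuple[int, int] = (512, 512),
                            cfg: Optional[AnalysisConfig] = None,
                            **plant_overrides) -> Dict[str, object]:
    """Plant >= `n_cells` cells, segment their droplets and count per cell.

    Returns detected and planted fractions of cells with >= 1 and >= 3
    droplets, plus the per-cell count table.
    """
    cfg = cfg or AnalysisConfig()
    plant = ImagingPlant(cells_per_field=cells_per_field,
                         count_law=count_law, diameter_law=diameter_law,
                         field_shape=field_shape, **plant_overrides)
    per_cell_all = []
    planted_counts = []
    field = 0
    total = 0
    while total < n_cells:
        stack, mask, gt = generate_ld_image_stack(plant, seed=seed + field)
        labels, table = measure_stack(stack, plant.pixel_size_um, cfg)
        per_cell, _summ = count_lds_per_cell(
            labels, mask, table, pixel_size=plant.pixel_size_um)
        per_cell_all.append(per_cell)
        counts = gt.droplets.groupby("cell_id").size()
        counts = counts.reindex(gt.cells["cell_id"], fill_value=0)
        planted_counts.extend(counts.tolist())
        total += len(per_cell)
        field += 1
    per_cell = pd.concat(per_cell_all, ignore_index=True).iloc[:n_cells]
    planted = np.asarray(planted_counts)[:n_cells]
    return {
        "per_cell": per_cell,
        "detected_frac_ge1": float((per_cell["n_lds"] >= 1).mean()),
        "detected_frac_ge3": float((per_cell["n_lds"] >= 3).mean()),
        "planted_frac_ge1": float((planted >= 1).mean()),
        "planted_frac_ge3": float((planted >= 3).mean()),
        "n_cells": int(len(per_cell)),
        "n_fields": field,
    }
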