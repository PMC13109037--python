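"""Three-criterion density screening and analysis-density selection.

At each edge density K, a subject's binarized network is screened for
(i) connectedness — more than 80% of nodes in the largest component,
(ii) modular organization — modularity Q above 0.3, and
(iii) small-world organization — sigma above 1.
A density qualifies when more than a majority (default 50%) of networks pass
all three; the analysis density is the mean of the maximal contiguous run of
qualifying densities, rounded half-away-from-zero to the grid's two-decimal
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .idscn_builder import round_half_away

CONNECTEDNESS_THRESHOLD = 0.8
MODULARITY_THRESHOLD = 0.3
SMALL_WORLD_THRESHOLD = 1.0

_REQUIRED = (
    "subject_id",
    "density",
    "largest_component_fraction",
    "modularity_q",
    "small_worldness",
)


def evaluate_criteria(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-density pass fractions of the three screening criteria.

    ``metrics`` holds one row per subject per density with columns
    ``subject_id``, ``density``, ``largest_component_fraction``,
    ``modularity_q`` and ``small_worldness``; every subject must appear at
    every density. Returns a frame indexed by density with columns
    ``frac_connected``, ``frac_modular``, ``frac_small_world``,
    ``frac_pass_all`` and ``n_networks``. All criteria are strict
    inequalities.
    """
    missing_cols = [c for c in _REQUIRED if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"metrics table lacks columns: {missing_cols}")
    if metrics.empty:
        raise ValueError("metrics table is empty")
    subjects = metrics["subject_id"].unique()
    densities = np.sort(metrics["density"].unique())
    counts = metrics.groupby(["subject_id", "density"]).size()
    if counts.max() > 1:
        raise ValueError(f"duplicate metric rows: {list(counts[counts > 1].index)}")
    expected = len(subjects) * len(densities)
    if len(counts) != expected:
        full = pd.MultiIndex.from_product([subjects, densities])
        missing = full.difference(counts.index)
        raise ValueError(f"missing metric cells (subject, density): {list(missing)}")

    frame = metrics.assign(
        connected=metrics["largest_component_fraction"] > CONNECTEDNESS_THRESHOLD,
        modular=metrics["modularity_q"] > MODULARITY_THRESHOLD,
        small_world=metrics["small_worldness"] > SMALL_WORLD_THRESHOLD,
    )
    frame = frame.assign(
        pass_all=frame["connected"] & frame["modular"] & frame["small_world"]
    )
    grouped = frame.groupby("density")
    table = pd.DataFrame(
        {
            "frac_connected": grouped["connected"].mean(),
            "frac_modular": grouped["modular"].mean(),
            "frac_small_world": grouped["small_world"].mean(),
            "frac_pass_all": grouped["pass_all"].mean(),
            "n_networks": grouped.size(),
        }
    ).sort_index()
    return table


@dataclass
class DensitySelection:
    k_low: float
    k_high: float
    k_selected: float
    retained: np.ndarray
    pass_fraction_at_selected: float


def select_density_range(
    table: pd.DataFrame, majority: float = 0.5
) -> DensitySelection:
    """Pick the analysis density from the criteria table.

    The retained range is the maximal contiguous run of densities whose
    all-criteria pass fraction exceeds ``majority``; on a length tie the
    lower-density run wins. The selected density is the mean of the retained
    grid values rounded half-away-from-zero to 2 decimals.
    """
    densities = np.asarray(table.index, dtype=float)
    passing = (table["frac_pass_all"] > majority).to_numpy()
    if not passing.any():
        raise ValueError("no admissible density range: no density passes the majority rule")

    runs: list[tuple[int, int]] = []  # [start, stop) index pairs
    start = None
    for idx, flag in enumerate(passing):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            runs.append((start, idx))
            start = None
    if start is not None:
        runs.append((start, len(passing)))
    lengths = [stop - begin for begin, stop in runs]
    begin, stop = runs[int(np.argmax(lengths))]  # argmax ties -> earliest (lower K)

    retained = densities[begin:stop]
    k_selected = round_half_away(float(retained.mean()), 2)
    nearest = densities[np.argmin(np.abs(densities - k_selected))]
    pass_at_selected = float(table["frac_pass_all"].loc[nearest])
    return DensitySelection(
        k_low=float(retained[0]),
        k_high=float(retained[-1]),
        k_selected=float(k_selected),
        retained=retained,
        pass_fraction_at_selected=pass_at_selected,
    )
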