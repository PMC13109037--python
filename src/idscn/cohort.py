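"""Cohort container shared by the simulator and the table loaders.

A cohort couples a per-subject covariate table (group, age, sex, education,
global mean cortical thickness) with a subjects x regions matrix of mean
regional cortical thickness (mm). Downstream stages only ever see this
bundle, so validation lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Desikan-Killiany cortical parcellation, 34 regions per hemisphere.
DK_REGIONS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "frontalpole", "insula",
)

#: Covariates entering the normative residualization, in design-matrix order.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "age", "sex", "education", "global_mean_thickness",
)

GROUP_CONTROL = "HC"
GROUP_SMOKER = "SM"


@dataclass
class CohortBundle:
    """Per-subject covariates plus the regional thickness matrix.

    Parameters
    ----------
    subjects
        Indexed by subject id; columns ``group``, ``age``, ``sex``,
        ``education``, ``global_mean_thickness``.
    thickness
        Indexed by subject id (same order as ``subjects``); one column per
        cortical region, values in mm.
    module_partition
        Optional ground-truth region-to-module assignment (only set by the
        simulator; ``None`` for loaded data).
    """

    subjects: pd.DataFrame
    thickness: pd.DataFrame
    module_partition: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.subjects.index.equals(self.thickness.index):
            raise ValueError("subject ids of covariate and thickness tables differ")
        if self.subjects.index.has_duplicates:
            dupes = self.subjects.index[self.subjects.index.duplicated()].unique()
            raise ValueError(f"duplicate subject ids: {list(dupes)}")
        groups = set(self.subjects["group"].unique())
        if not groups <= {GROUP_CONTROL, GROUP_SMOKER}:
            raise ValueError(
                f"group labels must be {GROUP_CONTROL}/{GROUP_SMOKER}, got {sorted(groups)}"
            )
        values = self.thickness.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("thickness matrix contains non-finite values")
        if np.any(values <= 0):
            bad = self.thickness.index[(values <= 0).any(axis=1)]
            raise ValueError(f"non-positive thickness for subjects {list(bad)}")
        if "global_mean_thickness" not in self.subjects.columns:
            self.subjects = self.subjects.assign(
                global_mean_thickness=values.mean(axis=1)
            )
        else:
            gmt = self.subjects["global_mean_thickness"].to_numpy(dtype=float)
            if np.max(np.abs(gmt - values.mean(axis=1))) > 1e-10:
                raise ValueError(
                    "global_mean_thickness does not equal the row mean of thickness"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return self.thickness.shape[1]

    @property
    def regions(self) -> list[str]:
        return list(self.thickness.columns)

    @property
    def groups(self) -> pd.Series:
        return self.subjects["group"]

    def hc_mask(self) -> np.ndarray:
        """Boolean mask over subjects selecting the healthy-control group."""
        return (self.subjects["group"] == GROUP_CONTROL).to_numpy()
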