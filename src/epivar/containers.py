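"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = frozenset(str(c) for c in range(1, 23))


@dataclass
class MarkerMatrix:
    """Sample x marker value matrix plus its manifest.

    ``values`` is a DataFrame indexed by sample id with one column per
    marker.  ``manifest`` has columns ``id``, ``chr``, ``pos``, ``set``
    (``"methylation"`` or ``"genotype"``), one row per marker, in column
    order.  ``standardized`` records whether each column has been scaled
    to mean 0, variance 1 (population convention) over non-missing
    entries.
    """

    values: pd.DataFrame
    manifest: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        man_ids = list(self.manifest["id"])
        col_ids = list(self.values.columns)
        if man_ids != col_ids:
            raise ValueError("manifest ids must match value columns in order")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, ids) -> "MarkerMatrix":
        ids = list(ids)
        man = self.manifest.set_index("id").loc[ids].reset_index()
        return MarkerMatrix(self.values[ids].copy(), man, self.standardized)

    def subset_set(self, set_label: str) -> "MarkerMatrix":
        keep = self.manifest.loc[self.manifest["set"] == set_label, "id"]
        return self.subset_markers(keep)

    def check_standardized(self, tol: float = 1e-8) -> bool:
        x = self.values.to_numpy(float)
        mu = np.nanmean(x, axis=0)
        var = np.nanvar(x, axis=0)
        return bool(np.all(np.abs(mu) < tol) and np.all(np.abs(var - 1) < tol))


@dataclass
class PosteriorDraws:
    """Retained Gibbs iterations for one- or two-set mixture regression.

    Arrays are stacked over retained draws (all chains combined):

    - ``beta``: (draws, p) effect sizes, exactly 0 when the marker sits
      in the spike.
    - ``components``: (draws, p) int mixture indicator, 0 = spike.
    - ``sigma2_g``: (draws, n_sets) per-set effect-variance scale.
    - ``sigma2_e``: (draws,) residual variance.
    - ``pi``: (draws, n_sets, K+1) mixture proportions incl. spike.
    - ``chain``: (draws,) chain id of each draw.
    """

    beta: np.ndarray
    components: np.ndarray
    sigma2_g: np.ndarray
    sigma2_e: np.ndarray
    pi: np.ndarray
    chain: np.ndarray
    marker_ids: list
    set_labels: list
    set_index: np.ndarray  # (p,) which set each marker belongs to
    standardized_input: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nz = self.beta != 0.0
        incl = self.components != 0
        if not np.array_equal(nz, incl):
            raise ValueError("beta nonzero iff component indicator nonzero")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_markers(self) -> int:
        return self.beta.shape[1]

    def markers_of_set(self, set_label: str) -> np.ndarray:
        s = self.set_labels.index(set_label)
        return np.flatnonzero(self.set_index == s)
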