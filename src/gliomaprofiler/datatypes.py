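"""Core data containers shared across the pipeline.

Two containers cross module boundaries and therefore live here:

* :class:`EventTable` — one flow-cytometry panel's worth of per-event
  fluorescence intensities, the unit of gating.
* :class:`ExpressionStudy` — a genes × samples log2 expression matrix with a
  control/tumor group label per sample, the unit of differential-expression,
  GO-enrichment and subtype analyses.

Gene identifiers are case-sensitive opaque symbols throughout; no alias
normalisation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a documented precondition or schema."""


CONTROL = "control"
TUMOR = "tumor"


@dataclass
class EventTable:
    """Per-event fluorescence intensities for one panel/condition.

    Parameters
    ----------
    data
        Events in rows, one column per fluorescence channel; intensities are
        positive reals in arbitrary units (linear scale).
    panel
        Panel name, e.g. ``"myeloid"``, ``"tcell"``, ``"mdsc"``.
    condition
        ``"naive"``, ``"sham"`` or ``"glioma"``.
    compartment
        ``"brain"`` or ``"blood"``.
    day
        Day after implantation (8, 14, 15 or 21) or ``None``.
    stain
        ``"antibody"`` for the specific stain, ``"isotype"`` for the matched
        isotype control.
    """

    data: pd.DataFrame
    panel: str = "unknown"
    condition: str = "naive"
    compartment: str = "brain"
    day: int | None = None
    stain: str = "antibody"

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValidationError("event table must contain at least one event")
        values = self.data.to_numpy(dtype=float)
        if not np.all(values > 0):
            raise ValidationError("fluorescence intensities must be strictly positive")
        if self.stain not in ("antibody", "isotype"):
            raise ValidationError(f"unknown stain type {self.stain!r}")
        self.data.index.name = "event_id"

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def require_channels(self, channels) -> None:
        missing = [c for c in channels if c not in self.data.columns]
        if missing:
            raise ValidationError(
                f"panel {self.panel!r} is missing required channel(s) {missing}; "
                f"available: {self.channels}"
            )


@dataclass
class ExpressionStudy:
    """Genes × samples log2 expression matrix with group labels.

    ``matrix`` rows are genes (unique identifiers in the index), columns are
    samples. ``groups`` maps every sample to ``"control"`` or ``"tumor"``.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    name: str = "study"

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifier(s): {dupes[:5]}")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.loc[self.matrix.columns]
        bad = sorted(set(self.groups.unique()) - {CONTROL, TUMOR})
        if bad:
            raise ValidationError(
                f"group labels must be '{CONTROL}' or '{TUMOR}', got {bad}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    def group_columns(self, label: str) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == label]

    @property
    def control_samples(self) -> list[str]:
        return self.group_columns(CONTROL)

    @property
    def tumor_samples(self) -> list[str]:
        return self.group_columns(TUMOR)

    def require_group_sizes(self, minimum: int = 2) -> None:
        nc, nt = len(self.control_samples), len(self.tumor_samples)
        if nc < minimum or nt < minimum:
            raise ValidationError(
                f"need at least {minimum} samples per group, got "
                f"{nc} control / {nt} tumor"
            )
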