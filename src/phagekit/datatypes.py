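"""Shared containers for liquid infection assays.

A :class:`Treatment` identifies one arm of a plate experiment (strain, phage
multiplicity of infection, antibiotic and dose); an :class:`ODTimeSeries`
holds a single replicate's optical-density trajectory under one treatment on
a uniform time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance for checking that a time grid is uniform
_GRID_TOL = 1e-9


@dataclass(frozen=True)
class Treatment:
    """One experimental arm: a strain exposed to phage and/or antibiotic.

    Parameters
    ----------
    strain_id:
        Bacterial strain label (e.g. ``"AB01"``).
    moi:
        Phage input multiplicity (pfu per cfu); 0 means no phage.
    antibiotic:
        Antibiotic name, or ``None`` for no antibiotic.
    concentration:
        Antibiotic concentration in mg/l; must be 0 iff ``antibiotic`` is None.
    """

    strain_id: str
    moi: float = 0.0
    antibiotic: str | None = None
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.moi < 0:
            raise ValueError(f"moi must be >= 0, got {self.moi}")
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration}"
            )
        if (self.antibiotic is None) != (self.concentration == 0):
            raise ValueError(
                "antibiotic is None iff concentration == 0; got "
                f"antibiotic={self.antibiotic!r}, "
                f"concentration={self.concentration}"
            )

    @property
    def label(self) -> str:
        ab = f"{self.antibiotic}@{self.concentration:g}" if self.antibiotic else "none"
        return f"{self.strain_id}|moi={self.moi:g}|{ab}"


@dataclass
class ODTimeSeries:
    """One replicate's OD590 trajectory under one treatment.

    ``times`` is a uniform grid in hours starting at 0; ``od`` are the
    matching OD590 readings. The standard 16 h plate-reader assay has 49
    points spaced 20 min (dt = 1/3 h) apart.
    """

    treatment: Treatment
    replicate: int
    times: np.ndarray
    od: np.ndarray
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(steps - steps[0])) > _GRID_TOL:
                raise ValueError("times must form a uniform grid")
            if self.dt == 0.0:
                self.dt = float(steps[0])
            elif abs(self.dt - steps[0]) > _GRID_TOL:
                raise ValueError(
                    f"declared dt={self.dt} inconsistent with grid "
                    f"spacing {steps[0]}"
                )
        if not np.all(np.isfinite(self.od)) or np.any(self.od < 0):
            raise ValueError("od readings must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.times)
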