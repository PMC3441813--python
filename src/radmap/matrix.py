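"""The clones-by-markers call matrix, the central data container.

Calls are coded 0 = absent, 1 = present, 2 = ambiguous, following the
scoring convention of bead-array RH genotyping where dots close to the
intensity threshold cannot be called either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

ABSENT = 0
PRESENT = 1
AMBIGUOUS = 2


@dataclass
class RHCallMatrix:
    """Presence/absence/ambiguous calls for a radiation-hybrid panel.

    Parameters
    ----------
    clones : ordered clone identifiers (rows).
    markers : ordered marker identifiers (columns).
    calls : int array of shape (n_clones, n_markers) over {0, 1, 2}.
    """

    clones: list[str]
    markers: list[str]
    calls: np.ndarray
    _marker_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.clones), len(self.markers)):
            raise ValueError(
                f"call array shape {self.calls.shape} does not match "
                f"{len(self.clones)} clones x {len(self.markers)} markers")
        bad = ~np.isin(self.calls, (ABSENT, PRESENT, AMBIGUOUS))
        if bad.any():
            raise ValueError("calls must be coded 0 (absent), 1 (present) "
                             "or 2 (ambiguous)")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker identifiers")
        if len(set(self.clones)) != len(self.clones):
            raise ValueError("duplicate clone identifiers")
        self._marker_index = {m: j for j, m in enumerate(self.markers)}

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def vector(self, marker: str) -> np.ndarray:
        """Per-clone calls for one marker."""
        return self.calls[:, self._marker_index[marker]]

    def subset_markers(self, markers: Sequence[str]) -> "RHCallMatrix":
        """A new matrix restricted to ``markers``, in the given order."""
        idx = [self._marker_index[m] for m in markers]
        return RHCallMatrix(list(self.clones), list(markers),
                            self.calls[:, idx].copy())

    def subset_clones(self, clones: Sequence[str]) -> "RHCallMatrix":
        index = {c: i for i, c in enumerate(self.clones)}
        idx = [index[c] for c in clones]
        return RHCallMatrix(list(clones), list(self.markers),
                            self.calls[idx, :].copy())

    def presence_fraction(self) -> float:
        """Fraction of informative (non-ambiguous) calls that are present."""
        informative = self.calls != AMBIGUOUS
        n_inf = int(informative.sum())
        if n_inf == 0:
            raise ValueError("matrix has no informative calls")
        return float((self.calls == PRESENT).sum() / n_inf)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RHCallMatrix):
            return NotImplemented
        return (self.clones == other.clones
                and self.markers == other.markers
                and np.array_equal(self.calls, other.calls))
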