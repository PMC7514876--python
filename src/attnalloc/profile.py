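"""Value profiles: named interface sections with fuzzy importance degrees.

A supervisory human-machine interface is partitioned into meaningful
sections (in eye-tracking terms, areas of interest). Each section carries a
membership degree of importance ``V`` in ``[0, 1)`` — a fuzzy-set grade,
typically elicited from domain experts, expressing how critical that
section's information is for the monitoring task. The profile is the only
free input of the allocation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["ValueProfile"]


@dataclass(frozen=True)
class ValueProfile:
    """Ordered sections ``(label, V)`` with ``0 <= V < 1`` and unique labels.

    ``V = 1`` is rejected by default because the value-priority transform
    ``-ln(1 - V)`` diverges there; pass ``allow_unit=True`` to admit it,
    in which case downstream allocation treats a unit-importance section as
    absorbing all attention (the limiting behavior of the model).
    """

    labels: tuple[str, ...]
    V: np.ndarray
    allow_unit: bool = field(default=False, compare=False)

    def __init__(
        self,
        sections: Iterable[tuple[str, float]] | None = None,
        *,
        labels: Sequence[str] | None = None,
        V: Sequence[float] | None = None,
        allow_unit: bool = False,
    ) -> None:
        if sections is not None:
            pairs = list(sections)
            labels = [str(lab) for lab, _ in pairs]
            V = [float(v) for _, v in pairs]
        if labels is None or V is None:
            raise ValueError("provide sections or both labels and V")
        labels = tuple(str(lab) for lab in labels)
        values = np.asarray(V, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("profile needs at least one section")
        if len(labels) != values.size:
            raise ValueError("labels and V lengths differ")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise ValueError(f"duplicate section labels: {dupes}")
        hi = 1.0 if allow_unit else np.nextafter(1.0, 0.0)
        for lab, v in zip(labels, values):
            if not (0.0 <= v <= hi):
                bound = "[0, 1]" if allow_unit else "[0, 1)"
                raise ValueError(f"section {lab!r}: V={v} outside {bound}")
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "V", values)
        object.__setattr__(self, "allow_unit", allow_unit)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(self.labels, self.V.tolist()))

    @property
    def sections(self) -> list[tuple[str, float]]:
        return list(self)

    def permuted(self, order: Sequence[int]) -> "ValueProfile":
        """Profile with sections reordered by index sequence ``order``."""
        idx = list(order)
        if sorted(idx) != list(range(len(self))):
            raise ValueError("order must be a permutation of section indices")
        return ValueProfile(
            labels=[self.labels[i] for i in idx],
            V=self.V[idx],
            allow_unit=self.allow_unit,
        )


#: The four-section subway building-automation (BAS) monitoring profile:
#: air intake/outtake fans in the station hall and on the platform, with
#: expert-elicited importance degrees.
BAS_PROFILE = ValueProfile(
    [
        ("intake@hall", 0.1),
        ("outtake@hall", 0.3),
        ("outtake@platform", 0.7),
        ("intake@platform", 0.9),
    ]
)

__all__.append("BAS_PROFILE")
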