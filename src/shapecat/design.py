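"""Stimulus designs: condition ids crossed with shape and category factors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import DegenerateModelError, ValidationError

FACTORS = ("shape", "category")


@dataclass(frozen=True)
class StimulusDesign:
    """A labelled stimulus set with a shape factor and a category factor.

    Parameters
    ----------
    condition_ids
        Unique condition identifiers, one per stimulus, in canonical order.
        Every pattern matrix and RDM in an analysis is aligned to this order.
    shape_labels, category_labels
        Factor level labels, one per condition. Each factor must have at
        least two levels for model RDMs and decoding audits to be defined.
    """

    condition_ids: tuple[str, ...]
    shape_labels: tuple[str, ...]
    category_labels: tuple[str, ...]

    def __init__(
        self,
        condition_ids: Sequence[str],
        shape_labels: Sequence[str],
        category_labels: Sequence[str],
    ):
        object.__setattr__(self, "condition_ids", tuple(str(c) for c in condition_ids))
        object.__setattr__(self, "shape_labels", tuple(str(s) for s in shape_labels))
        object.__setattr__(self, "category_labels", tuple(str(c) for c in category_labels))
        self._validate()

    def _validate(self) -> None:
        n = len(self.condition_ids)
        if n < 3:
            raise ValidationError(f"a design needs at least 3 conditions, got {n}")
        if len(self.shape_labels) != n or len(self.category_labels) != n:
            raise ValidationError(
                "condition_ids, shape_labels and category_labels must have equal "
                f"length; got {n}, {len(self.shape_labels)}, {len(self.category_labels)}"
            )
        if len(set(self.condition_ids)) != n:
            dupes = sorted({c for c in self.condition_ids if self.condition_ids.count(c) > 1})
            raise ValidationError(f"duplicate condition ids: {dupes}")
        for factor in FACTORS:
            if len(set(self.labels(factor))) < 2:
                raise DegenerateModelError(
                    f"factor {factor!r} has a single level; at least 2 required"
                )

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def labels(self, factor: str) -> tuple[str, ...]:
        """Return the label sequence for ``factor`` ('shape' or 'category')."""
        if factor == "shape":
            return self.shape_labels
        if factor == "category":
            return self.category_labels
        raise ValidationError(f"unknown factor {factor!r}; expected one of {FACTORS}")

    def levels(self, factor: str) -> tuple[str, ...]:
        """Distinct levels of ``factor`` in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels(factor):
            seen.setdefault(lab, None)
        return tuple(seen)

    def other_factor(self, factor: str) -> str:
        self.labels(factor)  # validates the name
        return "category" if factor == "shape" else "shape"
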