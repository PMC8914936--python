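"""Template matching for action classification.

The distortion between a test vector ``T`` and a reference template ``R``
of the same length is the plain sum of squared element-wise differences,

.. math:: D[T, R] = \\sum_n (t_n - r_n)^2 .

This is the diagonal (no-warping) special case of dynamic time warping:
the action feature vectors compared here always have the same fixed length
(18 values), so no warping path search is needed.  When the lengths do
differ, the shorter sequence is expanded to the longer length by linear
interpolation over a uniform index grid before the sum is taken.

The predicted action is the template with the smallest distortion; ties
break in the fixed action order (socks, shoes, laces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import SchemaError
from .trace import ANGLE_AXES, PARTS

#: Recognized actions in fixed (tie-break) order.
ACTIONS: tuple[str, ...] = ("socks", "shoes", "laces")

_DEFAULT_TEMPLATE_RESOURCE = "default_templates.json"


def pointwise_distortion(t_n: float, r_m: float) -> float:
    """Squared difference between one pair of eigenvalues."""
    return (float(t_n) - float(r_m)) ** 2


def _expand(values: np.ndarray, length: int) -> np.ndarray:
    """Linearly interpolate a sequence onto a uniform grid of ``length``."""
    if values.size == length:
        return values
    if values.size == 1:
        return np.full(length, values[0])
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, values)


def dtw_distance(T: Iterable[float], R: Iterable[float]) -> float:
    """Distortion between a test vector and a reference template.

    Equal lengths: exact element-wise sum of squared differences.  Unequal
    lengths: the shorter sequence is linearly expanded to the longer length
    first.  Always >= 0, symmetric, and 0 for identical sequences.
    """
    t = np.asarray(list(T) if not isinstance(T, np.ndarray) else T, dtype=float)
    r = np.asarray(list(R) if not isinstance(R, np.ndarray) else R, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("sequences must be non-empty")
    n = max(t.size, r.size)
    t = _expand(t, n)
    r = _expand(r, n)
    d = t - r
    return float(np.dot(d, d))


@dataclass(frozen=True)
class ReferenceTemplate:
    """One action's reference vector (18 values in the fixed channel order:
    unit-1 deltas for (upper_arm, lower_arm, hand) x (roll, pitch, yaw),
    then unit-2 deltas in the same order)."""

    action: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.size < 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("template values must be non-empty and finite")


@dataclass
class TemplateLibrary:
    """Reference templates, one per action, all the same length."""

    templates: dict[str, ReferenceTemplate]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("template library must not be empty")
        lengths = {t.values.size for t in self.templates.values()}
        if len(lengths) != 1:
            raise ValueError("all templates must have the same length")

    @property
    def actions(self) -> tuple[str, ...]:
        # fixed order first, then any user-defined extras
        known = [a for a in ACTIONS if a in self.templates]
        extra = [a for a in self.templates if a not in ACTIONS]
        return tuple(known + extra)

    # -- JSON interchange: {action: {part: {axis: [unit1, unit2]}}} --------

    @classmethod
    def from_dict(cls, payload: dict, provenance: str = "") -> "TemplateLibrary":
        actions = payload.get("actions", payload)
        templates: dict[str, ReferenceTemplate] = {}
        for action, parts in actions.items():
            unit1, unit2 = [], []
            for part in PARTS:
                if part not in parts:
                    raise SchemaError(f"template {action!r} is missing part {part!r}")
                for axis in ANGLE_AXES:
                    pair = parts[part].get(axis)
                    if pair is None or len(pair) != 2:
                        raise SchemaError(
                            f"template {action!r} {part}.{axis} must list "
                            "[unit1, unit2] values"
                        )
                    unit1.append(float(pair[0]))
                    unit2.append(float(pair[1]))
            templates[action] = ReferenceTemplate(
                action=action, values=np.array(unit1 + unit2)
            )
        return cls(templates=templates,
                   provenance=payload.get("provenance", provenance))

    def to_dict(self) -> dict:
        actions: dict[str, dict] = {}
        for action, tmpl in self.templates.items():
            v = tmpl.values
            actions[action] = {
                part: {
                    axis: [float(v[3 * i + j]), float(v[9 + 3 * i + j])]
                    for j, axis in enumerate(ANGLE_AXES)
                }
                for i, part in enumerate(PARTS)
            }
        return {"provenance": self.provenance, "actions": actions}


def default_templates() -> TemplateLibrary:
    """The bundled default reference library (three 18-value templates)."""
    text = (
        resources.files("limbintent")
        .joinpath("data", _DEFAULT_TEMPLATE_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return TemplateLibrary.from_dict(json.loads(text))


def load_templates(path: str | Path | None) -> TemplateLibrary:
    """Load a library from a JSON file; ``None`` or ``"default"`` gives the
    bundled defaults."""
    if path is None or str(path) == "default":
        return default_templates()
    with open(path, encoding="utf-8") as fh:
        return TemplateLibrary.from_dict(json.load(fh), provenance=str(path))


@dataclass(frozen=True)
class ClassificationResult:
    """Predicted action with the per-action distortions and the margin
    (runner-up distance minus best distance; ``inf`` with one template)."""

    action: str
    distances: dict[str, float]
    margin: float

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "distances": {a: float(d) for a, d in self.distances.items()},
            "margin": float(self.margin),
        }


def classify_action(vector: Iterable[float], library: TemplateLibrary) -> ClassificationResult:
    """Minimum-distortion classification of an 18-value action vector."""
    v = np.asarray(list(vector) if not isinstance(vector, np.ndarray) else vector,
                   dtype=float)
    distances = {
        action: dtw_distance(v, library.templates[action].values)
        for action in library.actions
    }
    ordered = sorted(distances.items(),
                     key=lambda kv: (kv[1], library.actions.index(kv[0])))
    best_action, best = ordered[0]
    margin = (ordered[1][1] - best) if len(ordered) > 1 else float("inf")
    return ClassificationResult(action=best_action, distances=distances, margin=margin)
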