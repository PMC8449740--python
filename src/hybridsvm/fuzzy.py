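"""Fuzzy memberships, Sugeno inference and the self-tuning rule base.

Two crisp inputs drive the per-particle adaptation:

* ``delta`` — distance to the global best, fuzzified as Same/Near/Far by
  piecewise-linear memberships with breakpoints at 0.2, 0.4 and 0.6 of the
  search-space diagonal; the three memberships form a partition of unity.
* ``phi`` — the normalized fitness increment in [-1, 1] (negative means the
  particle improved), fuzzified as Better/Same/Worse, also a partition of
  unity.

Each of the five outputs (inertia ``w``, social ``c_soc``, cognitive
``c_cog``, velocity-clamp coefficients ``lam`` and ``eta``) has three crisp
levels and is defuzzified by zero-order Sugeno inference: the
activation-weighted mean of the fired levels.  The rule table and level
grid are data (``rulebase.yaml``), not code, so a corrected transcription
never changes this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "FuzzySettings",
    "FuzzyRuleBase",
    "delta_memberships",
    "phi_memberships",
    "sugeno_output",
    "default_rulebase",
    "load_rulebase",
]

OUTPUT_VARS = ("w", "c_soc", "c_cog", "lam", "eta")
DELTA_LABELS = ("Same", "Near", "Far")
PHI_LABELS = ("Better", "Same", "Worse")


@dataclass(frozen=True)
class FuzzySettings:
    """Per-particle, per-iteration PSO coefficients."""

    w: float
    c_soc: float
    c_cog: float
    lam: float
    eta: float

    def __post_init__(self) -> None:
        if not self.eta > self.lam:
            raise ValueError("max-velocity coefficient eta must exceed lam")


def delta_memberships(delta: float, delta_max: float) -> tuple[float, float, float]:
    """(Same, Near, Far) memberships of a distance ``delta`` in [0, delta_max].

    Breakpoints: d1 = 0.2, d2 = 0.4, d3 = 0.6 of ``delta_max``.  Same is a
    left-shoulder trapezoid, Near a triangle peaking at d2, Far a
    right-shoulder trapezoid; together they sum to 1 everywhere.
    """
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    if delta < 0 or delta > delta_max:
        raise ValueError("delta must lie in [0, delta_max]")
    d1, d2, d3 = 0.2 * delta_max, 0.4 * delta_max, 0.6 * delta_max
    if delta < d1:
        same, near, far = 1.0, 0.0, 0.0
    elif delta < d2:
        same = (d2 - delta) / (d2 - d1)
        near = (delta - d1) / (d2 - d1)
        far = 0.0
    elif delta < d3:
        same = 0.0
        near = (d3 - delta) / (d3 - d2)
        far = (delta - d2) / (d3 - d2)
    else:
        same, near, far = 0.0, 0.0, 1.0
    return same, near, far


def phi_memberships(phi: float) -> tuple[float, float, float]:
    """(Better, Same, Worse) memberships of a fitness increment in [-1, 1].

    Values slightly outside [-1, 1] are clamped with a warning (float
    round-off guard); larger excursions are a caller bug but clamp too.
    """
    if phi < -1 or phi > 1:
        warnings.warn(f"phi={phi} outside [-1, 1]; clamping", stacklevel=2)
        phi = min(1.0, max(-1.0, phi))
    better = -phi if phi < 0 else 0.0
    same = 1.0 - abs(phi)
    worse = phi if phi > 0 else 0.0
    return better, same, worse


def sugeno_output(activations, outputs, fallback: float | None = None) -> float:
    """Zero-order Sugeno defuzzification: sum(rho*z) / sum(rho).

    With all activations zero the ``fallback`` level is returned (the
    caller passes the variable's Medium level); a zero total without a
    fallback is an error, as is an empty rule list.
    """
    activations = list(activations)
    outputs = list(outputs)
    if not activations or len(activations) != len(outputs):
        raise ValueError("need matching, nonempty activation/output lists")
    if any(a < 0 for a in activations):
        raise ValueError("activations must be nonnegative")
    total = sum(activations)
    if total == 0:
        if fallback is None:
            raise ValueError("all activations zero and no fallback level")
        return fallback
    return sum(a * z for a, z in zip(activations, outputs)) / total


@dataclass
class FuzzyRuleBase:
    """Declarative rule table + Table-of-levels grid.

    ``rules``: list of (input, label, output, level) tuples with input in
    {delta, phi}; ``levels``: {output: {Low/Medium/High: value}}.
    """

    rules: list[tuple[str, str, str, str]]
    levels: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for var in OUTPUT_VARS:
            if var not in self.levels:
                raise ValueError(f"missing level grid for {var!r}")
            inputs = {r[0] for r in self.rules if r[2] == var}
            if not {"delta", "phi"} <= inputs:
                raise ValueError(f"{var!r} needs rules over both delta and phi")
        for inp, label, out, level in self.rules:
            ok = DELTA_LABELS if inp == "delta" else PHI_LABELS if inp == "phi" else None
            if ok is None or label not in ok or out not in OUTPUT_VARS \
                    or level not in ("Low", "Medium", "High"):
                raise ValueError(f"malformed rule {(inp, label, out, level)}")

    def infer(self, delta: float, delta_max: float, phi: float) -> FuzzySettings:
        """Defuzzified settings for one particle at one iteration."""
        dm = dict(zip(DELTA_LABELS, delta_memberships(delta, delta_max)))
        pm = dict(zip(PHI_LABELS, phi_memberships(phi)))
        out: dict[str, float] = {}
        for var in OUTPUT_VARS:
            acts, zs = [], []
            for inp, label, ovar, level in self.rules:
                if ovar != var:
                    continue
                acts.append(dm[label] if inp == "delta" else pm[label])
                zs.append(self.levels[var][level])
            out[var] = sugeno_output(acts, zs, fallback=self.levels[var]["Medium"])
        return FuzzySettings(**out)


def load_rulebase(path: str) -> FuzzyRuleBase:
    """Load a rule base from a YAML file (same schema as the shipped one)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _parse_rulebase(raw)


def _parse_rulebase(raw: dict) -> FuzzyRuleBase:
    rules = [(r["input"], r["label"], r["output"], r["level"]) for r in raw["rules"]]
    levels = {k: dict(v) for k, v in raw["levels"].items()}
    return FuzzyRuleBase(rules=rules, levels=levels)


def default_rulebase() -> FuzzyRuleBase:
    """The rule base shipped with the package (``rulebase.yaml``)."""
    text = resources.files(__package__).joinpath("rulebase.yaml").read_text()
    return _parse_rulebase(yaml.safe_load(text))
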