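"""Named loss breakdowns for arithmetic-level testing.

Every composite objective in the package reports its terms through a
:class:`LossReport`, so tests can verify to machine precision that the
optimized total equals the weighted sum of the published components.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class LossReport:
    """Raw loss terms, their weights, and the weighted total."""

    terms: dict = field(default_factory=dict)      # name -> raw value
    weights: dict = field(default_factory=dict)    # name -> weight (default 1)
    extras: dict = field(default_factory=dict)     # diagnostics (arrays allowed)

    def add(self, name: str, value: float, weight: float = 1.0):
        self.terms[name] = float(value)
        self.weights[name] = float(weight)

    def weighted(self, name: str) -> float:
        return self.weights.get(name, 1.0) * self.terms[name]

    @property
    def total(self) -> float:
        return sum(self.weighted(k) for k in self.terms)

    def __getitem__(self, name: str) -> float:
        return self.terms[name]

    def as_dict(self) -> dict:
        out = {k: self.terms[k] for k in self.terms}
        out["total"] = self.total
        return out
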