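"""Result containers shared by the driver and the report I/O."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class CriterionResult:
    """Outcome of one earliness criterion on one dataset.

    ``curve[i]`` is the criterion's score at split point ``n = i + 1``;
    for the conditional-entropy criterion rejected split points carry
    ``+inf``.  ``earliness_percent`` is ``n / L * 100``.
    """

    criterion: str
    n: int
    earliness_percent: float
    curve: list[float]


@dataclass
class MCECResult:
    """Full output of an earliness sweep: per-criterion choices plus the
    conditional-entropy gap curve and a dataset summary."""

    n_instances: int
    length: int
    n_features: int
    n_classes: int
    entropy_gap_curve: list[float] = field(default_factory=list)
    criteria: dict[str, CriterionResult] = field(default_factory=dict)
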