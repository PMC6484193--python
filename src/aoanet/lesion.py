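"""Hidden-unit lesioning of trained networks and the damage experiment.

A lesion removes a random fraction of the hidden layer.  Two methods:

``zero_weights``
    every incoming and outgoing weight and the bias of each selected unit
    is set to 0; with zero outgoing weights the unit contributes nothing,
    so this removes it from the functional circuit.
``add_noise``
    independent zero-mean Gaussian noise (sd ``noise_sd``) is added to
    every incoming and outgoing weight of each selected unit.

The experiment sweeps a severity grid over many independent lesion samples
and compares the damage done to early- versus late-learned words.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .metrics import evaluate
from .network import NetworkState

METHODS = ("zero_weights", "add_noise")


@dataclass(frozen=True)
class LesionSpec:
    """Severity fraction, lesion method and replication settings."""

    severity: float
    method: str = "zero_weights"
    noise_sd: float = 0.5
    n_samples: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _n_lesioned(severity: float, n_hidden: int) -> int:
    # round-half-up so 5%/10%/20% of 100 units give exactly 5/10/20
    n = int(np.floor(severity * n_hidden + 0.5))
    if n > n_hidden:
        raise ValueError("severity selects more units than the hidden layer has")
    return n


def lesion_network(net: NetworkState, spec: LesionSpec, sample_index: int) -> NetworkState:
    """Return a lesioned copy of ``net``; the input state is never mutated.

    The unit subset is drawn from a per-sample seeded stream, so different
    ``sample_index`` values give independent lesions and the same index
    reproduces the same lesion.
    """
    H = net.n_hidden
    n = _n_lesioned(spec.severity, H)
    out = net.copy()
    if n == 0:
        return out
    rng = np.random.default_rng([spec.seed, sample_index])
    units = rng.choice(H, size=n, replace=False)
    if spec.method == "zero_weights":
        out.W_ih[units, :] = 0.0
        out.b_h[units] = 0.0
        out.W_ho[:, units] = 0.0
    else:  # add_noise
        out.W_ih[units, :] += rng.normal(0.0, spec.noise_sd, size=(n, net.n_in))
        out.W_ho[:, units] += rng.normal(0.0, spec.noise_sd, size=(net.n_out, n))
    return out


@dataclass
class LesionResult:
    """Per-sample per-item post-lesion errors plus group aggregates."""

    per_item: pd.DataFrame  # sample, method, severity, word_id, grade, sse, correct
    summary: pd.DataFrame  # method, severity, group, mean_sse, mean_correct
    early_ids: Tuple[str, ...] = ()
    late_ids: Tuple[str, ...] = ()

    def gap(self, method: str, severity: float) -> float:
        """(late - early) mean SSE at one grid point, averaged over samples."""
        s = self.summary
        sel = s[(s["method"] == method) & (np.isclose(s["severity"], severity))]
        late = sel.loc[sel["group"] == "late", "mean_sse"].iloc[0]
        early = sel.loc[sel["group"] == "early", "mean_sse"].iloc[0]
        return float(late - early)


def run_lesion_experiment(
    net: NetworkState,
    lexicon: Lexicon,
    early_ids: Sequence[str],
    late_ids: Sequence[str],
    severities: Iterable[float] = (0.05, 0.10, 0.20),
    methods: Iterable[str] = METHODS,
    n_samples: int = 20,
    noise_sd: float = 0.5,
    seed: int = 0,
    include_baseline: bool = True,
) -> LesionResult:
    """Sweep severity x method x sample over a trained network.

    Each grid cell evaluates all early and late items on an independently
    lesioned copy.  A severity-0 baseline row (the intact network) is
    included by default so damage can be read as a difference from it.
    """
    early_ids = tuple(early_ids)
    late_ids = tuple(late_ids)
    eval_lex = lexicon.subset(list(early_ids) + list(late_ids))
    group = {w: "early" for w in early_ids}
    group.update({w: "late" for w in late_ids})

    sev_list = sorted(set(float(s) for s in severities) | ({0.0} if include_baseline else set()))
    rows: List[pd.DataFrame] = []
    for method in methods:
        for severity in sev_list:
            spec = LesionSpec(
                severity=severity, method=method, noise_sd=noise_sd, n_samples=n_samples, seed=seed
            )
            for sample in range(n_samples):
                lesioned = lesion_network(net, spec, sample)
                res = evaluate(lesioned, eval_lex)
                res.insert(0, "sample", sample)
                res.insert(1, "method", method)
                res.insert(2, "severity", severity)
                rows.append(res)
    per_item = pd.concat(rows, ignore_index=True)
    per_item["group"] = per_item["word_id"].map(group)

    summary = (
        per_item.groupby(["method", "severity", "group"], as_index=False)
        .agg(mean_sse=("sse", "mean"), mean_correct=("correct", "mean"))
        .sort_values(["method", "severity", "group"])
        .reset_index(drop=True)
    )
    return LesionResult(per_item=per_item, summary=summary, early_ids=early_ids, late_ids=late_ids)
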