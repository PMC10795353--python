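"""BCI performance metrics and offline re-analysis sweeps.

Accuracy is the fraction of blocks whose selected answer matched the
intended one.  Because a session has a limited number of blocks, the
empirical chance level is the exact inverse binomial CDF at p = 0.5 (no
normal approximation): with 100 blocks and an alpha risk of 1% an
accuracy has to exceed 62% to count as above chance.

The offline sweeps reproduce the re-analysis protocol: greedy backward
electrode selection on the cross-validated accuracy, block-duration
truncation, and stimulus-pool restriction (Total / STD / DEV / YES / NO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import decoder as _decoder
from .io_formats import PipelineConfig
from .stimgen import Stream

__all__ = [
    "ChanceLevel",
    "chance_level",
    "accuracy_report",
    "backward_select",
    "sweep_block_length",
    "sweep_stimulus_pool",
]


@dataclass(frozen=True)
class ChanceLevel:
    n_trials: int
    alpha: float
    threshold_count: int
    threshold_accuracy: float


def chance_level(n_trials: int, alpha: float) -> ChanceLevel:
    """Empirical chance level from the exact binomial inverse CDF.

    ``threshold_count`` is the smallest k with CDF(k; n, 0.5) >= 1 - alpha
    (the binoinv convention); accuracies strictly above
    ``threshold_count / n`` are significant at level alpha.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    k = int(binom.ppf(1 - alpha, n_trials, 0.5))
    return ChanceLevel(
        n_trials=n_trials,
        alpha=alpha,
        threshold_count=k,
        threshold_accuracy=k / n_trials,
    )


def accuracy_report(decisions, truths, alpha: float = 0.01) -> dict:
    """Accuracy with its exact-binomial significance flag.

    ``decisions`` and ``truths`` are equal-length sequences of YES/NO
    answers (or BlockDecision objects for ``decisions``).
    """
    dec = [
        d.decision if isinstance(d, _decoder.BlockDecision) else Stream(d)
        for d in decisions
    ]
    tru = [Stream(t) for t in truths]
    if len(dec) != len(tru):
        raise ValueError("decisions and truths must have equal length")
    if not dec:
        raise ValueError("empty decision list")
    n = len(dec)
    n_correct = sum(d is t for d, t in zip(dec, tru))
    cl = chance_level(n, alpha)
    return {
        "n": n,
        "n_correct": n_correct,
        "accuracy": n_correct / n,
        "alpha": alpha,
        "chance_threshold_count": cl.threshold_count,
        "chance_threshold_accuracy": cl.threshold_accuracy,
        "verdict": "above chance" if n_correct > cl.threshold_count else "chance level",
    }


def backward_select(
    recording,
    targets,
    config: PipelineConfig | None = None,
    min_channels: int = 1,
) -> pd.DataFrame:
    """Greedy backward electrode selection on calibration CV accuracy.

    Starting from the full montage, repeatedly drop the channel whose
    removal maximizes (or least harms) the block-LOO accuracy, until
    ``min_channels`` remain.  Test data never enters the criterion.  Ties
    are broken by channel-name order.  Returns one row per step with the
    removed channel, the remaining montage and its accuracy (step 0 is
    the full montage).
    """
    config = config or PipelineConfig()
    remaining = list(config.channels)
    if len(remaining) < 2:
        raise ValueError("need >= 2 channels")
    acc0, _ = _decoder.cross_validate(
        recording, targets, config, channels=remaining
    )
    rows = [
        {"step": 0, "removed": None, "n_channels": len(remaining),
         "channels": tuple(remaining), "accuracy": acc0}
    ]
    step = 0
    while len(remaining) > min_channels:
        step += 1
        best = None
        for ch in sorted(remaining):
            subset = [c for c in remaining if c != ch]
            acc, _ = _decoder.cross_validate(
                recording, targets, config, channels=subset
            )
            if best is None or acc > best[1]:
                best = (ch, acc)
        remaining = [c for c in remaining if c != best[0]]
        rows.append(
            {"step": step, "removed": best[0], "n_channels": len(remaining),
             "channels": tuple(remaining), "accuracy": best[1]}
        )
    return pd.DataFrame(rows)


def sweep_block_length(
    recording,
    targets,
    k_grid,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy with blocks truncated to k stimuli/stream.

    The truncated inputs feed the full pipeline (filters and classifiers
    refit per fold).  The effective stimulation duration of a truncated
    block is ``2 k x SOA``.
    """
    config = config or PipelineConfig()
    ps = _decoder.prepare_session(recording, config, targets)
    rows = []
    for k in k_grid:
        acc, _ = _decoder.cross_validate(ps.truncate(int(k)), config=config, on_missing='pin')
        rows.append({"k_per_stream": int(k), "accuracy": acc})
    return pd.DataFrame(rows)


def sweep_stimulus_pool(
    recording,
    targets,
    pools=("TOTAL", "STD", "DEV", "YES", "NO"),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy per stimulus pool.

    Excluded conditions' classifiers are pinned to 0.5 (they drop out of
    the posterior product); the TOTAL pool is exactly the unrestricted
    decoder.
    """
    config = config or PipelineConfig()
    for pool in pools:
        if pool not in _decoder.POOLS:
            raise ValueError(f"unknown pool {pool!r}")
    ps = _decoder.prepare_session(recording, config, targets)
    # one unrestricted CV; pools re-fuse the stored per-condition
    # posteriors with excluded classifiers pinned to 0.5
    _, decisions = _decoder.cross_validate(ps, config=config, pool="TOTAL")
    truths = [ps.blocks[d.block].target for d in decisions]
    rows = []
    for pool in pools:
        active = {
            _decoder.CONDITION_NAMES[c] for c in _decoder.POOLS[pool]
        }
        hits = 0
        for d, truth in zip(decisions, truths):
            fused = _decoder.fuse_posteriors(
                {k: (v if k in active else 0.5) for k, v in d.posteriors.items()}
            )
            decided = Stream.YES if fused > 0.5 else Stream.NO
            hits += decided is truth
        rows.append({"pool": pool, "accuracy": hits / len(decisions)})
    return pd.DataFrame(rows)
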