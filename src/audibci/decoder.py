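"""Block-level yes/no decoding with four fused probabilistic classifiers.

Each block contains four response conditions — standard "yes", standard
"no", deviant "yes", deviant "no".  For each condition the epochs of the
block are averaged, spatially filtered by the condition-kind's xDAWN
bank, and flattened into one feature vector; one binary Gaussian
classifier per condition outputs the posterior probability that the
block's target was YES.  Under a uniform prior and conditional
independence of the four response types, the block posterior is the
normalized product of the four classifier posteriors, and the class with
posterior > 0.5 is selected.

The processing chain mirrors the online system: causal 0.5–20 Hz
band-pass, anti-aliased x10 decimation (the feature decimation applied
once to the continuous signal before epoching, which also keeps the
xDAWN least-squares design tractable at 1000 Hz), per-kind epoch
windows, per-subject filter count chosen by block leave-one-out
cross-validation on the calibration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.covariance import ledoit_wolf

from .io_formats import PipelineConfig
from .preproc import bandpass, decimate_recording
from .stimgen import CODE_TO_CONDITION, Kind, Stream
from .synthdata import Recording
from .xdawn import SpatialFilterBank, apply_filters, fit_xdawn

logger = logging.getLogger("audibci")

__all__ = [
    "CONDITIONS",
    "POOLS",
    "ConditionClassifier",
    "DecoderModel",
    "BlockDecision",
    "PreparedSession",
    "prepare_session",
    "build_features",
    "fit",
    "decide_block",
    "cross_validate",
    "replay_online",
    "fuse_posteriors",
    "loo_accuracy_by_candidate",
]

#: the four response conditions, (stream, kind)
CONDITIONS: list[tuple[Stream, Kind]] = [
    (Stream.YES, Kind.STANDARD),
    (Stream.NO, Kind.STANDARD),
    (Stream.YES, Kind.DEVIANT),
    (Stream.NO, Kind.DEVIANT),
]

CONDITION_NAMES = {
    (Stream.YES, Kind.STANDARD): "STD_YES",
    (Stream.NO, Kind.STANDARD): "STD_NO",
    (Stream.YES, Kind.DEVIANT): "DEV_YES",
    (Stream.NO, Kind.DEVIANT): "DEV_NO",
}

#: stimulus pools: which conditions' classifiers participate in fusion
POOLS: dict[str, list[tuple[Stream, Kind]]] = {
    "TOTAL": list(CONDITIONS),
    "STD": [c for c in CONDITIONS if c[1] is Kind.STANDARD],
    "DEV": [c for c in CONDITIONS if c[1] is Kind.DEVIANT],
    "YES": [c for c in CONDITIONS if c[0] is Stream.YES],
    "NO": [c for c in CONDITIONS if c[0] is Stream.NO],
}


# ---------------------------------------------------------------------------
# session preparation (shared online/offline front end)


@dataclass
class PreparedBlock:
    data: np.ndarray  # (n_channels, n_samples) filtered+decimated
    target: Stream | None
    #: (sample, stream, kind, within-stream ordinal)
    events: list[tuple[int, Stream, Kind, int]]


@dataclass
class PreparedSession:
    blocks: list[PreparedBlock]
    channels: list[str]
    fs: float
    windows: dict[Kind, int]  # samples

    def truncate(self, k: int) -> "PreparedSession":
        """Keep only the first k stimuli of each stream of every block."""
        n_per_stream = max(e[3] for b in self.blocks for e in b.events) + 1
        if not (1 <= k <= n_per_stream):
            raise ValueError(f"k must be in 1..{n_per_stream}")
        blocks = [
            PreparedBlock(
                data=b.data,
                target=b.target,
                events=[e for e in b.events if e[3] < k],
            )
            for b in self.blocks
        ]
        return PreparedSession(blocks, self.channels, self.fs, self.windows)

    def subset(self, indices) -> "PreparedSession":
        return PreparedSession(
            [self.blocks[i] for i in indices], self.channels, self.fs, self.windows
        )


def prepare_session(
    recording: Recording,
    config: PipelineConfig,
    targets: list[Stream] | None = None,
    filter_mode: str = "causal",
    channels: list[str] | None = None,
) -> PreparedSession:
    """Filter, decimate and segment a recording into per-block data.

    ``channels`` restricts the montage (for electrode-selection
    analyses) before any processing.
    """
    if channels is not None:
        recording = recording.pick(channels)
    rec = bandpass(recording, config.band_low, config.band_high, mode=filter_mode)
    rec = decimate_recording(rec, config.decim)
    fs = rec.fs
    windows = {
        Kind.STANDARD: int(round(config.window_std_s * fs)),
        Kind.DEVIANT: int(round(config.window_dev_s * fs)),
    }
    max_win = max(windows.values())

    bounds = rec.block_bounds()
    blocks: list[PreparedBlock] = []
    for b, (start, end) in enumerate(bounds):
        stop = min(end + 1, rec.n_samples)
        data = rec.signal[:, start:stop]
        counters = {Stream.YES: 0, Stream.NO: 0}
        events = []
        for sample, code in rec.events:
            cond = CODE_TO_CONDITION.get(code)
            if cond is None or not (start <= sample < stop):
                continue
            stream, kind = cond
            rel = sample - start
            if rel + windows[kind] > data.shape[1]:
                logger.warning("dropping epoch beyond block bounds (block %d)", b)
                counters[stream] += 1
                continue
            events.append((rel, stream, kind, counters[stream]))
            counters[stream] += 1
        target = Stream(targets[b]) if targets is not None and b < len(targets) else None
        blocks.append(PreparedBlock(data=data, target=target, events=events))
    return PreparedSession(
        blocks=blocks, channels=list(rec.channels), fs=fs, windows=windows
    )


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ConditionClassifier:
    """Binary Gaussian classifier for one response condition.

    Class-conditional Gaussians with shared (shrunk) covariance over the
    per-block condition-average features; equal priors.  ``posterior``
    returns P(target = YES | feature).
    """

    condition: tuple[Stream, Kind]
    mean_yes: np.ndarray
    mean_no: np.ndarray
    weights: np.ndarray  # precision @ (mean_yes - mean_no)
    bias: float
    shrinkage: float

    @classmethod
    def fit(
        cls,
        features: np.ndarray,
        is_yes: np.ndarray,
        condition: tuple[Stream, Kind],
        shrinkage: float | str = "lw",
    ) -> "ConditionClassifier":
        features = np.asarray(features, float)
        is_yes = np.asarray(is_yes, bool)
        if is_yes.all() or (~is_yes).all():
            raise ValueError("single-class calibration: both targets required")
        mu1 = features[is_yes].mean(axis=0)
        mu0 = features[~is_yes].mean(axis=0)
        resid = features.copy()
        resid[is_yes] -= mu1
        resid[~is_yes] -= mu0
        if shrinkage == "lw":
            cov, coef = ledoit_wolf(resid, assume_centered=True)
        else:
            coef = float(shrinkage)
            emp = resid.T @ resid / len(resid)
            mu = np.trace(emp) / emp.shape[0]
            cov = (1 - coef) * emp + coef * mu * np.eye(emp.shape[0])
        w = np.linalg.solve(cov, mu1 - mu0)
        b = -0.5 * float((mu1 + mu0) @ w)
        return cls(
            condition=condition,
            mean_yes=mu1,
            mean_no=mu0,
            weights=w,
            bias=b,
            shrinkage=float(coef),
        )

    def posterior(self, feature: np.ndarray) -> float:
        z = float(self.weights @ feature + self.bias)
        return float(expit(z))

    def to_dict(self) -> dict:
        return {
            "condition": CONDITION_NAMES[self.condition],
            "mean_yes": self.mean_yes.tolist(),
            "mean_no": self.mean_no.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "shrinkage": self.shrinkage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionClassifier":
        cond = {v: k for k, v in CONDITION_NAMES.items()}[d["condition"]]
        return cls(
            condition=cond,
            mean_yes=np.asarray(d["mean_yes"]),
            mean_no=np.asarray(d["mean_no"]),
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            shrinkage=float(d["shrinkage"]),
        )


def fuse_posteriors(posteriors: dict, prior_yes: float = 0.5) -> float:
    """Normalized product of per-condition posteriors.

    Each classifier was trained with the uniform prior, so the prior is
    divided out of each posterior and re-applied once overall; with the
    default uniform prior this reduces to
    ``prod(p) / (prod(p) + prod(1 - p))``.  Pinning a classifier at 0.5
    removes it from the product.
    """
    logit = np.log(prior_yes) - np.log(1 - prior_yes)
    for p in posteriors.values():
        p = min(max(float(p), 1e-12), 1 - 1e-12)
        logit += np.log(p) - np.log(1 - p)
    return float(expit(logit))


@dataclass
class BlockDecision:
    block: int
    posteriors: dict  # condition name -> P(YES | feature)
    fused: float  # P(YES | block)
    decision: Stream
    undecided: bool = False
    truth: Stream | None = None

    @property
    def correct(self) -> bool | None:
        return None if self.truth is None else self.decision is self.truth

    def to_dict(self) -> dict:
        return {
            "block": self.block,
            "posteriors": {k: float(v) for k, v in self.posteriors.items()},
            "fused": self.fused,
            "decision": self.decision.value,
            "undecided": self.undecided,
            "truth": None if self.truth is None else self.truth.value,
        }


# ---------------------------------------------------------------------------
# model


@dataclass
class DecoderModel:
    banks: dict[Kind, SpatialFilterBank]
    classifiers: dict[tuple[Stream, Kind], ConditionClassifier]
    n_filters: int
    windows: dict[Kind, int]
    fs: float
    channels: list[str]
    config: PipelineConfig
    prior_yes: float = 0.5
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "banks": {k.value: b.to_dict() for k, b in self.banks.items()},
            "classifiers": [c.to_dict() for c in self.classifiers.values()],
            "n_filters": self.n_filters,
            "windows": {k.value: int(v) for k, v in self.windows.items()},
            "fs": self.fs,
            "channels": self.channels,
            "config": self.config.to_dict(),
            "prior_yes": self.prior_yes,
            "threshold": self.threshold,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderModel":
        clfs = [ConditionClassifier.from_dict(c) for c in d["classifiers"]]
        return cls(
            banks={Kind(k): SpatialFilterBank.from_dict(b) for k, b in d["banks"].items()},
            classifiers={c.condition: c for c in clfs},
            n_filters=int(d["n_filters"]),
            windows={Kind(k): int(v) for k, v in d["windows"].items()},
            fs=float(d["fs"]),
            channels=list(d["channels"]),
            config=PipelineConfig(**d["config"]),
            prior_yes=float(d["prior_yes"]),
            threshold=float(d["threshold"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DecoderModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# features


def _condition_average(
    block: PreparedBlock, windows: dict[Kind, int], condition: tuple[Stream, Kind]
) -> np.ndarray:
    stream, kind = condition
    w = windows[kind]
    eps = [
        block.data[:, s : s + w]
        for s, st, kd, _ in block.events
        if st is stream and kd is kind
    ]
    if not eps:
        raise ValueError(f"missing condition {CONDITION_NAMES[condition]} in block")
    return np.mean(eps, axis=0)


def build_features(
    block: PreparedBlock,
    banks: dict[Kind, SpatialFilterBank],
    n_filters: int,
    windows: dict[Kind, int],
    conditions=None,
) -> dict[tuple[Stream, Kind], np.ndarray]:
    """Per-condition feature vectors: filtered condition-average, flattened."""
    out = {}
    for cond in conditions or CONDITIONS:
        avg = _condition_average(block, windows, cond)
        proj = apply_filters(avg[None], banks[cond[1]], n_filters)[0]
        if not np.all(np.isfinite(proj)):
            raise ValueError("non-finite features")
        out[cond] = proj.ravel()
    return out


def _fit_banks(
    ps: PreparedSession, config: PipelineConfig
) -> dict[Kind, SpatialFilterBank]:
    """One attended-vs-ignored bank per stimulus kind on the whole session."""
    banks = {}
    data = np.hstack([b.data for b in ps.blocks])
    offsets = np.cumsum([0] + [b.data.shape[1] for b in ps.blocks[:-1]])
    for kind in Kind:
        events = []
        for off, b in zip(offsets, ps.blocks):
            if b.target is None:
                raise ValueError("calibration blocks need targets")
            for s, st, kd, _ in b.events:
                if kd is kind:
                    events.append((off + s, int(st is b.target)))
        banks[kind] = fit_xdawn(
            data,
            events,
            window_s=ps.windows[kind] / ps.fs,
            contrast="attended_vs_ignored",
            fs=ps.fs,
            channels=ps.channels,
        )
    return banks


def _has_condition(block: PreparedBlock, cond: tuple[Stream, Kind]) -> bool:
    return any(st is cond[0] and kd is cond[1] for _, st, kd, _ in block.events)


def _fit_classifiers(
    ps: PreparedSession,
    banks: dict[Kind, SpatialFilterBank],
    n_filters: int,
    config: PipelineConfig,
) -> dict[tuple[Stream, Kind], ConditionClassifier]:
    """One classifier per condition, on the blocks containing it.

    A condition absent from enough blocks to leave a single target class
    (possible under aggressive block truncation) is skipped; its
    posterior is pinned to 0.5 at decision time.
    """
    is_yes = np.array([b.target is Stream.YES for b in ps.blocks])
    out = {}
    for cond in CONDITIONS:
        rows = [i for i, b in enumerate(ps.blocks) if _has_condition(b, cond)]
        feats = np.stack(
            [
                build_features(ps.blocks[i], banks, n_filters, ps.windows, [cond])[cond]
                for i in rows
            ]
        )
        labels = is_yes[rows]
        if len(rows) < len(ps.blocks) and (labels.all() or not labels.any()):
            logger.warning(
                "condition %s missing from too many blocks; classifier skipped",
                CONDITION_NAMES[cond],
            )
            continue
        out[cond] = ConditionClassifier.fit(feats, labels, cond, config.shrinkage)
    return out


# ---------------------------------------------------------------------------
# fitting and decisions


def _fit_prepared(
    ps: PreparedSession, config: PipelineConfig, n_filters: int | None = None
) -> DecoderModel:
    if len(ps.blocks) < 2:
        raise ValueError("need >= 2 calibration blocks")
    banks = _fit_banks(ps, config)
    if n_filters is None:
        if config.n_xdawn_filters == "auto":
            candidates = list(
                range(1, min(config.max_auto_filters, len(ps.channels)) + 1)
            )
            acc = _loo_candidates(ps, config, candidates)
            n_filters = max(acc, key=lambda n: (acc[n], -n))
        else:
            n_filters = int(config.n_xdawn_filters)
    classifiers = _fit_classifiers(ps, banks, n_filters, config)
    return DecoderModel(
        banks=banks,
        classifiers=classifiers,
        n_filters=n_filters,
        windows=ps.windows,
        fs=ps.fs,
        channels=ps.channels,
        config=config,
    )


def fit(
    recording: Recording,
    targets: list[Stream],
    config: PipelineConfig | None = None,
    channels: list[str] | None = None,
) -> DecoderModel:
    """Calibrate the decoder on an instructed session.

    Requires at least 4 blocks with both targets represented.  With
    ``n_xdawn_filters='auto'`` the filter count is chosen by block
    leave-one-out cross-validation on the calibration data.
    """
    config = config or PipelineConfig()
    ps = prepare_session(recording, config, targets, channels=channels)
    if len(ps.blocks) < 4:
        raise ValueError("need >= 4 calibration blocks")
    return _fit_prepared(ps, config)


def decide_block(
    model: DecoderModel,
    block: PreparedBlock,
    block_index: int = 0,
    pool: str = "TOTAL",
    on_missing: str = "error",
) -> BlockDecision:
    """Fuse the four (or pooled subset of) classifier posteriors.

    Conditions outside the pool are pinned to 0.5 and therefore drop out
    of the product, as are conditions absent from the block (possible
    under truncation) when ``on_missing='pin'``.  A fused posterior of
    exactly 0.5 is an undecided tie, resolved as NO and flagged.
    """
    active = POOLS[pool]
    posteriors = {}
    for cond in CONDITIONS:
        name = CONDITION_NAMES[cond]
        usable = cond in active and cond in model.classifiers
        if usable and not _has_condition(block, cond):
            if on_missing == "pin":
                logger.warning("block %d: condition %s absent, pinned to 0.5",
                               block_index, name)
                usable = False
            else:
                raise ValueError(f"missing condition {name} in block")
        if usable:
            feats = build_features(
                block, model.banks, model.n_filters, model.windows, [cond]
            )
            posteriors[name] = model.classifiers[cond].posterior(feats[cond])
        else:
            posteriors[name] = 0.5
    fused = fuse_posteriors(posteriors, model.prior_yes)
    undecided = fused == model.threshold
    decision = Stream.YES if fused > model.threshold else Stream.NO
    return BlockDecision(
        block=block_index,
        posteriors=posteriors,
        fused=fused,
        decision=decision,
        undecided=undecided,
        truth=block.target,
    )


def _loo_candidates(
    ps: PreparedSession, config: PipelineConfig, candidates: list[int]
) -> dict[int, float]:
    """Block-LOO accuracy per candidate filter count (banks shared per fold)."""
    hits = {n: 0 for n in candidates}
    total = 0
    for i in range(len(ps.blocks)):
        train = ps.subset([j for j in range(len(ps.blocks)) if j != i])
        try:
            banks = _fit_banks(train, config)
        except ValueError:
            continue
        total += 1
        for n in candidates:
            clfs = _fit_classifiers(train, banks, n, config)
            model = DecoderModel(
                banks=banks,
                classifiers=clfs,
                n_filters=n,
                windows=ps.windows,
                fs=ps.fs,
                channels=ps.channels,
                config=config,
            )
            d = decide_block(model, ps.blocks[i], i)
            if d.correct:
                hits[n] += 1
    if total == 0:
        raise ValueError("no valid cross-validation folds")
    return {n: hits[n] / total for n in candidates}


def loo_accuracy_by_candidate(
    recording: Recording,
    targets: list[Stream],
    config: PipelineConfig | None = None,
    candidates: list[int] | None = None,
) -> dict[int, float]:
    config = config or PipelineConfig()
    ps = prepare_session(recording, config, targets)
    return _loo_candidates(ps, config, candidates or list(range(1, 6)))


def cross_validate(
    recording_or_session,
    targets: list[Stream] | None = None,
    config: PipelineConfig | None = None,
    pool: str = "TOTAL",
    channels: list[str] | None = None,
    on_missing: str = "error",
) -> tuple[float, list[BlockDecision]]:
    """Block-wise leave-one-out cross-validation of the calibration.

    For each held-out block the full model — spatial filters,
    classifiers, and (when ``n_xdawn_filters='auto'``) the filter count
    via a nested inner LOO — is refit on the remaining blocks.  Returns
    (accuracy, per-block decisions).
    """
    config = config or PipelineConfig()
    if isinstance(recording_or_session, PreparedSession):
        ps = recording_or_session
    else:
        ps = prepare_session(recording_or_session, config, targets, channels=channels)
    n = len(ps.blocks)
    if n < 2:
        raise ValueError("need >= 2 blocks")
    decisions = []
    for i in range(n):
        train = ps.subset([j for j in range(n) if j != i])
        try:
            model = _fit_prepared(train, config)
        except ValueError as exc:
            # degenerate fold (e.g. single-class training set): no usable
            # calibration means an uninformative posterior -> tie rule
            logger.warning("fold %d unfittable (%s); undecided", i, exc)
            decisions.append(
                BlockDecision(
                    block=i,
                    posteriors={name: 0.5 for name in CONDITION_NAMES.values()},
                    fused=0.5,
                    decision=Stream.NO,
                    undecided=True,
                    truth=ps.blocks[i].target,
                )
            )
            continue
        decisions.append(decide_block(model, ps.blocks[i], i, pool=pool, on_missing=on_missing))
    accuracy = float(np.mean([d.correct for d in decisions]))
    return accuracy, decisions


def replay_online(
    model: DecoderModel,
    recording: Recording,
    targets: list[Stream] | None = None,
    pool: str = "TOTAL",
) -> tuple[list[BlockDecision], list[float]]:
    """Causal block-by-block replay of a test session.

    Uses the causal filter path and emits decisions in block order with
    the running accuracy after each block, mirroring the online feedback
    loop.  Identical to batch decoding under the same filter mode.
    """
    ps = prepare_session(
        recording, model.config, targets, filter_mode="causal",
        channels=model.channels if model.channels != recording.channels else None,
    )
    decisions: list[BlockDecision] = []
    running: list[float] = []
    hits = 0
    for i, block in enumerate(ps.blocks):
        try:
            d = decide_block(model, block, i, pool=pool)
        except ValueError as exc:
            logger.warning("skipping block %d: %s", i, exc)
            continue
        decisions.append(d)
        if d.correct is not None:
            hits += int(d.correct)
            running.append(hits / len([x for x in decisions if x.correct is not None]))
        logger.info(
            "block %d: P(YES)=%.3f decision=%s truth=%s",
            i, d.fused, d.decision.value, d.truth.value if d.truth else "?",
        )
    return decisions, running
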