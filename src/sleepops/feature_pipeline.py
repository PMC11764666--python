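"""Epoch rebalancing and ordinal-feature extraction.

The preparation pipeline mirrors the study protocol: downsample the dominant
N2 class by half, augment the scarce N1 and W classes with epochs cut at the
midpoint between consecutive same-stage epochs, then drop the two epochs
flanking every stage transition.  From the balanced epochs four feature sets
are built:

========== ============================================== ========
set        content                                        columns
========== ============================================== ========
PE_C       normalized entropy H and complexity C at q=0         2
GWPE_GWPEC H and C at every q of the grid                      42
PDF        the 24 pattern probabilities at q=0                 24
GWPDF      all pattern probabilities at every q               504
========== ============================================== ========

(column counts for the default D=4, tau=1, q = -10..10 configuration).
Feature columns are named ``p_<pattern>_q<q>`` / ``H_q<q>`` / ``C_q<q>``,
e.g. ``p_0123_q-3`` or ``C_q2``; within GWPDF the q index varies in the
outer loop and the pattern in the inner one.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingSignalError
from .ordinal_core import (
    OrdinalConfig,
    _symbolize,
    _weighted_probs,
    enumerate_patterns,
    max_divergence,
)
from .sleep_io import META_COLUMNS, STAGES, LabeledEpoch, read_feature_frame, write_feature_frame

FEATURE_SETS = ("PE_C", "GWPE_GWPEC", "PDF", "GWPDF")

_EPOCH_SAMPLES = 3000  # default 30 s at 100 Hz


def _fmt_q(q: float) -> str:
    return f"{q:g}"


@dataclass
class FeatureTable:
    """Epochs-by-features matrix with stage labels and provenance.

    ``frame`` holds the meta columns (subject_id, start_sample, origin,
    stage) followed by the feature columns.
    """

    frame: pd.DataFrame
    feature_set: str
    config: OrdinalConfig

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["stage"].to_numpy()

    @property
    def training_frame(self) -> pd.DataFrame:
        """Features plus the stage label (the classifier's view)."""
        return self.frame[self.feature_names + ["stage"]]

    def to_csv(self, path: str | Path) -> None:
        write_feature_frame(self.frame, path)

    @classmethod
    def from_csv(
        cls, path: str | Path, feature_set: str, config: OrdinalConfig | None = None
    ) -> "FeatureTable":
        return cls(
            frame=read_feature_frame(path),
            feature_set=feature_set,
            config=config or OrdinalConfig(),
        )


# ---------------------------------------------------------------------------
# Rebalancing operations
# ---------------------------------------------------------------------------


def remove_boundary_epochs(epochs: list[LabeledEpoch]) -> list[LabeledEpoch]:
    """Drop the two epochs flanking every stage transition.

    At each label change between consecutive epochs (within a subject) the
    last epoch of the earlier run and the first epoch of the later run are
    removed; single-epoch runs can vanish entirely.
    """
    drop: set[int] = set()
    for i in range(len(epochs) - 1):
        a, b = epochs[i], epochs[i + 1]
        if a.subject_id == b.subject_id and a.stage != b.stage:
            drop.add(i)
            drop.add(i + 1)
    return [e for i, e in enumerate(epochs) if i not in drop]


def downsample_majority(
    epochs: list[LabeledEpoch],
    stage: str = "N2",
    fraction: float = 0.5,
    seed: int = 0,
) -> list[LabeledEpoch]:
    """Randomly retain ``ceil(n * fraction)`` epochs of the target stage.

    Sampling is uniform without replacement and deterministic given the seed;
    all other stages and the overall epoch order are untouched.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    target_idx = [i for i, e in enumerate(epochs) if e.stage == stage]
    n_keep = math.ceil(len(target_idx) * fraction)
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(target_idx, size=n_keep, replace=False)) if target_idx else set()
    return [e for i, e in enumerate(epochs) if e.stage != stage or i in keep]


def augment_midpoints(
    epochs: list[LabeledEpoch],
    signals: dict[str, np.ndarray],
    stages: frozenset[str] | set[str] = frozenset({"N1", "W"}),
    epoch_samples: int = _EPOCH_SAMPLES,
) -> list[LabeledEpoch]:
    """Add midpoint epochs between consecutive same-stage epoch pairs.

    For each pair of exactly contiguous epochs (start samples
    ``epoch_samples`` apart, same subject, same stage in ``stages``) a new
    epoch is cut from the continuous signal starting halfway into the first
    epoch.  Originals are retained; the output is sorted by subject and
    start sample, with augmented epochs between their parents.
    """
    out = list(epochs)
    for a, b in zip(epochs, epochs[1:]):
        if (
            a.subject_id == b.subject_id
            and a.stage == b.stage
            and a.stage in stages
            and b.start_sample - a.start_sample == epoch_samples
        ):
            signal = signals.get(a.subject_id)
            start = a.start_sample + epoch_samples // 2
            if signal is None or start + epoch_samples > signal.size:
                raise MissingSignalError(
                    f"cannot cut augmented window [{start}, {start + epoch_samples}) "
                    f"for subject {a.subject_id!r}"
                )
            out.append(
                LabeledEpoch(
                    samples=signal[start : start + epoch_samples],
                    stage=a.stage,
                    subject_id=a.subject_id,
                    start_sample=start,
                    origin="augmented",
                )
            )
    out.sort(key=lambda e: (e.subject_id, e.start_sample))
    return out


def rebalance(
    epochs: list[LabeledEpoch],
    signals: dict[str, np.ndarray],
    downsample_stage: str = "N2",
    downsample_fraction: float = 0.5,
    augment_stages: frozenset[str] | set[str] = frozenset({"N1", "W"}),
    seed: int = 0,
    epoch_samples: int = _EPOCH_SAMPLES,
) -> list[LabeledEpoch]:
    """Full rebalancing pass: N2 downsampling, N1/W midpoint augmentation,
    then boundary-epoch removal, in that order."""
    epochs = downsample_majority(epochs, downsample_stage, downsample_fraction, seed)
    epochs = augment_midpoints(epochs, signals, augment_stages, epoch_samples)
    return remove_boundary_epochs(epochs)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def feature_columns(feature_set: str, config: OrdinalConfig) -> list[str]:
    """Stable column names of a feature set under a configuration."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}, got {feature_set!r}")
    patterns = [p.name for p in enumerate_patterns(config.D)]
    if feature_set == "GWPDF":
        return [f"p_{name}_q{_fmt_q(q)}" for q in config.q_grid for name in patterns]
    if feature_set == "PDF":
        return [f"p_{name}_q0" for name in patterns]
    if feature_set == "GWPE_GWPEC":
        return [f"{kind}_q{_fmt_q(q)}" for q in config.q_grid for kind in ("H", "C")]
    return ["H_q0", "C_q0"]


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _epoch_features(samples: np.ndarray, feature_set: str, config: OrdinalConfig) -> list[float]:
    M = config.n_patterns
    pattern_idx, weights = _symbolize(samples, config.D, config.tau)
    q_values = config.q_grid if feature_set in ("GWPDF", "GWPE_GWPEC") else (0.0,)
    row: list[float] = []
    log_M = math.log(M)
    for q in q_values:
        probs, _ = _weighted_probs(pattern_idx, weights, q, M)
        if feature_set in ("GWPDF", "PDF"):
            row.extend(probs.tolist())
        else:
            S = _entropy(probs)
            H = S / log_M
            mid = 0.5 * (probs + 1.0 / M)
            jsd = _entropy(mid) - 0.5 * (S + log_M)
            C = (jsd / max_divergence(M)) * H
            row.extend((H, C))
    return row


def build_feature_table(
    epochs: list[LabeledEpoch],
    feature_set: str,
    config: OrdinalConfig | None = None,
) -> FeatureTable:
    """Compute one of the four feature sets for every epoch.

    Each epoch is symbolized once; the q grid then reweights the same
    segments, so results match independent per-q calls to the core API.
    Degenerate epochs (all segments zero-variance) are reported together in a
    single error listing the offending rows.
    """
    config = config or OrdinalConfig()
    columns = feature_columns(feature_set, config)
    rows = []
    meta = []
    failures = []
    for i, epoch in enumerate(epochs):
        try:
            rows.append(_epoch_features(epoch.samples, feature_set, config))
        except ValueError as exc:
            failures.append((i, epoch.subject_id, epoch.start_sample, str(exc)))
            continue
        meta.append((epoch.subject_id, epoch.start_sample, epoch.origin, epoch.stage))
    if failures:
        detail = "; ".join(
            f"epoch {i} (subject {s}, start {st}): {msg}" for i, s, st, msg in failures
        )
        raise ValueError(f"{len(failures)} epochs failed feature extraction: {detail}")

    frame = pd.DataFrame(meta, columns=META_COLUMNS)
    frame = pd.concat([frame, pd.DataFrame(rows, columns=columns)], axis=1)
    return FeatureTable(frame=frame, feature_set=feature_set, config=config)


def build_all_feature_tables(
    epochs: list[LabeledEpoch], config: OrdinalConfig | None = None
) -> dict[str, FeatureTable]:
    """All four feature sets from one symbolization-friendly pass."""
    return {fs: build_feature_table(epochs, fs, config) for fs in FEATURE_SETS}


# ---------------------------------------------------------------------------
# Stage-median q-profiles
# ---------------------------------------------------------------------------

_COLUMN_RE = re.compile(r"^(?P<quantity>H|C|p_(?P<pattern>\d+))_q(?P<q>-?\d+(?:\.\d+)?)$")


def stage_median_profiles(
    table: FeatureTable, patterns: tuple[str, ...] = ("0123", "3210")
) -> pd.DataFrame:
    """Median feature value per stage and q, in tidy long format.

    For an entropy/complexity table the quantities are H and C; for a
    probability table they are the requested monotone-pattern probabilities
    (``p_0123`` and ``p_3210`` by default).  Columns of the result:
    ``stage``, ``quantity``, ``q``, ``median``.  Stages absent from the
    table are omitted with a warning.
    """
    keep_patterns = set(patterns)
    records = []
    for col in table.feature_names:
        m = _COLUMN_RE.match(col)
        if m is None:
            continue
        quantity = m.group("quantity")
        if m.group("pattern") is not None and m.group("pattern") not in keep_patterns:
            continue
        q = float(m.group("q"))
        medians = table.frame.groupby("stage", observed=True)[col].median()
        for stage, value in medians.items():
            records.append((stage, quantity, q, float(value)))

    present = {r[0] for r in records}
    missing = [s for s in STAGES if s not in present]
    if missing:
        warnings.warn(f"stages absent from table, omitted from profiles: {missing}")

    out = pd.DataFrame(records, columns=["stage", "quantity", "q", "median"])
    return out.sort_values(["quantity", "stage", "q"], ignore_index=True)
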