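"""Model evaluation: feature-table building, cross-validation, and the
artifact-removal comparison harness.

Cross-validation follows the repeated random-subsampling scheme: each of the
k folds draws an independent 90/10 split per class, fits the unimodal model
on the 90% and scores the held-out 10%, reporting per-class mean +/- SD and
delta.  (Classic partitioned k-fold is available via ``partitioned=True``.)

The cleaner-comparison harness scores raw recordings and each externally
supplied cleaning function with the same fitted model, feature set and
epoching, so the mean scores are directly comparable; the uncleaned baseline
is always included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import extract_feature_vector
from .io import ClassLabel, Recording, common_average_reference, segment_epochs
from .unimodal import UnimodalQualityModel, UnimodalQualityResults, delta_metric

logger = logging.getLogger(__name__)

__all__ = [
    "build_feature_table",
    "unimodal_feature_tables",
    "FoldReport",
    "cross_validate",
    "ComparisonReport",
    "compare_cleaners",
]


def build_feature_table(recordings: list[Recording], epoch_seconds: float,
                        label: ClassLabel | str,
                        car: bool = True) -> pd.DataFrame:
    """Per-channel-epoch feature table from a list of recordings.

    Applies common-average referencing (within each recording, over the
    channels it contains), segments into single-channel epochs, and extracts
    the canonical feature vector per epoch.  Constant epochs are skipped with
    a log message.  Key columns: subject, channel, epoch_start_s, class.
    """
    label = ClassLabel(label)
    rows = []
    for rec in recordings:
        ref = common_average_reference(rec) if car else rec
        for ep in segment_epochs(ref, epoch_seconds, mode="per_channel"):
            if np.ptp(ep.samples) == 0:
                logger.warning(
                    "skipping constant epoch %s @ %gs", ep.source_channel,
                    ep.start_time,
                )
                continue
            row = {
                "subject": rec.metadata.get("subject", ""),
                "channel": ep.source_channel,
                "epoch_start_s": ep.start_time,
                "class": label.value,
            }
            row.update(extract_feature_vector(ep.samples, ep.sampling_rate))
            rows.append(row)
    return pd.DataFrame(rows)


def unimodal_feature_tables(study: list[dict], epoch_seconds: float = 60.0,
                            car: bool = True) -> dict[ClassLabel, pd.DataFrame]:
    """Clean/raw/noise feature tables from a synthetic unimodal study."""
    return {
        ClassLabel.CLEAN: build_feature_table(
            [s["clean"] for s in study], epoch_seconds, ClassLabel.CLEAN, car),
        ClassLabel.RAW: build_feature_table(
            [s["raw"] for s in study], epoch_seconds, ClassLabel.RAW, car),
        ClassLabel.NOISE: build_feature_table(
            [s["noise"] for s in study], epoch_seconds, ClassLabel.NOISE, car),
    }


@dataclass
class FoldReport:
    """Per-fold result: class means +/- SD of held-out scores and delta."""

    fold: int
    class_means: dict[str, float]
    class_sds: dict[str, float]
    class_ns: dict[str, int]
    delta: float
    included_features: list[str]

    def as_row(self) -> dict:
        row = {"fold": self.fold, "delta": self.delta,
               "n_features": len(self.included_features)}
        for label in ("C", "R", "N"):
            row[f"mean_{label}"] = self.class_means[label]
            row[f"sd_{label}"] = self.class_sds[label]
            row[f"n_{label}"] = self.class_ns[label]
        return row


def cross_validate(tables: dict, k: int = 10, holdout_fraction: float = 0.10,
                   inclusion_threshold: float = 0.35, seed: int = 0,
                   partitioned: bool = False,
                   min_samples: int = 10) -> list[FoldReport]:
    """Repeated random-subsampling validation of the unimodal model.

    ``tables`` maps class labels to feature tables.  Each fold fits on a
    random (1 - holdout_fraction) share of every class and scores the
    held-out remainder.  With ``partitioned=True`` the folds are instead the
    k disjoint test blocks of a shuffled partition (holdout_fraction ignored).
    """
    tables = {ClassLabel(l): df.reset_index(drop=True)
              for l, df in tables.items()}
    rng = np.random.default_rng(seed)
    splits: list[dict[ClassLabel, np.ndarray]] = []
    if partitioned:
        perms = {l: rng.permutation(len(df)) for l, df in tables.items()}
        for i in range(k):
            splits.append({
                l: np.sort(perm[i::k]) for l, perm in perms.items()
            })
    else:
        for _ in range(k):
            split = {}
            for l, df in tables.items():
                n_test = max(1, int(round(holdout_fraction * len(df))))
                split[l] = np.sort(
                    rng.choice(len(df), size=n_test, replace=False)
                )
            splits.append(split)

    reports = []
    for i, split in enumerate(splits):
        train = {}
        test = {}
        for l, df in tables.items():
            mask = np.zeros(len(df), dtype=bool)
            mask[split[l]] = True
            train[l] = df[~mask]
            test[l] = df[mask]
        res = UnimodalQualityModel(
            train[ClassLabel.CLEAN], train[ClassLabel.RAW],
            train[ClassLabel.NOISE],
        ).fit(inclusion_threshold=inclusion_threshold, min_samples=min_samples)
        means, sds, ns = {}, {}, {}
        for l, df in test.items():
            q = res.score(df)
            means[l.value] = float(q.mean())
            sds[l.value] = float(q.std(ddof=1)) if len(q) > 1 else 0.0
            ns[l.value] = len(q)
        reports.append(FoldReport(
            fold=i,
            class_means=means, class_sds=sds, class_ns=ns,
            delta=delta_metric(means["C"], means["R"], means["N"]),
            included_features=res.included_features,
        ))
    return reports


def summarize_folds(reports: list[FoldReport]) -> pd.DataFrame:
    """Fold table plus an aggregate row (mean of per-fold means and SDs)."""
    df = pd.DataFrame([r.as_row() for r in reports])
    agg = df.drop(columns="fold").mean(numeric_only=True)
    agg["fold"] = "mean"
    return pd.concat([df, agg.to_frame().T], ignore_index=True)


@dataclass
class ComparisonReport:
    """Mean +/- SD unimodal score per cleaning method, raw baseline included."""

    table: pd.DataFrame  # index: method label; columns: mean, sd, n

    def ordering(self) -> list[str]:
        return list(self.table.sort_values("mean", ascending=False).index)


def compare_cleaners(raw_recordings: list[Recording], cleaners: dict,
                     results: UnimodalQualityResults,
                     epoch_seconds: float = 60.0,
                     car: bool = True) -> ComparisonReport:
    """Score raw recordings and each cleaned version with one fitted model.

    ``cleaners`` maps method labels to callables Recording -> Recording; the
    harness never implements any removal algorithm itself.  A cleaner that
    changes the channel count or sampling rate is rejected.
    """
    variants: dict[str, list[Recording]] = {"raw": list(raw_recordings)}
    for label, fn in cleaners.items():
        cleaned = []
        for rec in raw_recordings:
            out = fn(rec)
            if out.n_channels != rec.n_channels or \
                    out.sampling_rate != rec.sampling_rate:
                raise ValueError(
                    f"cleaner {label!r} changed channel count or rate"
                )
            cleaned.append(out)
        variants[label] = cleaned

    rows = {}
    for label, recs in variants.items():
        table = build_feature_table(recs, epoch_seconds, ClassLabel.RAW, car)
        q = results.score(table)
        rows[label] = {"mean": float(q.mean()),
                       "sd": float(q.std(ddof=1)), "n": len(q)}
    return ComparisonReport(table=pd.DataFrame(rows).T)
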