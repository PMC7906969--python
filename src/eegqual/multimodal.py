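"""Multimodal signal-quality scoring from two-class classifier probabilities.

When the noise source cannot be recorded by the same modality as the signal
(e.g. motion contaminating EEG), quality is scored from a classifier trained
to separate clean segments (label 1) from raw segments with the artifact
present (label 0).  Given the predicted class probabilities P_C and P_R of a
segment, the score is

    Q_M = 1/2 + (P_C - P_R)/2

(the two printed branches of the piecewise definition reduce to this single
expression), so (P_C, P_R) = (1, 0) scores 1, (0, 1) scores 0 and an
uncommitted (0.5, 0.5) scores 0.5.  The two probabilities are treated as free
numbers in [0, 1] and are not required to sum to one, so externally produced
probability files from any classifier can be scored.

The classifier itself is pluggable.  :class:`MultimodalQualityModel` ships a
lightweight reference classifier — multinomial logistic regression over
per-channel band-power summaries of each multichannel segment — sufficient to
exercise the scoring pathway end to end; any model producing (P_C, P_R) pairs
can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import DEFAULT_BANDS, band_powers, compute_periodogram
from .io import Epoch

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierProbabilities",
    "score_multimodal",
    "MultimodalQualityModel",
    "MultimodalQualityResults",
]


@dataclass(frozen=True)
class ClassifierProbabilities:
    """Predicted probabilities of the clean and raw classes, each in [0, 1]."""

    p_clean: float
    p_raw: float

    def __post_init__(self) -> None:
        for p in (self.p_clean, self.p_raw):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def score_multimodal(p_clean: float, p_raw: float) -> float:
    """Q_M = 1/2 + (P_C - P_R)/2, antisymmetric about 0.5."""
    p = ClassifierProbabilities(float(p_clean), float(p_raw))
    return 0.5 + (p.p_clean - p.p_raw) / 2.0


def _segment_features(epoch: Epoch) -> np.ndarray:
    """Per-channel summary features of a multichannel segment.

    Six relative band powers plus log total power per channel, flattened.
    """
    data = np.atleast_2d(epoch.samples)
    feats = []
    for ch in data:
        spec = compute_periodogram(ch, epoch.sampling_rate)
        total = float(np.sum(spec.power))
        if total <= 0:
            feats.extend([0.0] * (len(DEFAULT_BANDS) + 1))
            continue
        _, rel = band_powers(spec)
        feats.extend(rel[b.name] for b in DEFAULT_BANDS)
        feats.append(np.log10(total))
    return np.asarray(feats)


class MultimodalQualityModel:
    """Quality model trained on clean vs raw multichannel segments.

    Parameters
    ----------
    clean_epochs, raw_epochs
        Multichannel :class:`~eegqual.io.Epoch` lists; all epochs must share
        the channel count and length.  Classes are balanced before training
        by down-sampling the larger one with a seeded RNG.
    """

    MIN_EPOCHS = 20

    def __init__(self, clean_epochs: list[Epoch], raw_epochs: list[Epoch]):
        if not clean_epochs or not raw_epochs:
            raise ValueError("both classes need segments; got a single class")
        if len(clean_epochs) < self.MIN_EPOCHS or len(raw_epochs) < self.MIN_EPOCHS:
            raise ValueError(
                f"need >= {self.MIN_EPOCHS} segments per class, got "
                f"{len(clean_epochs)} clean / {len(raw_epochs)} raw"
            )
        shapes = {np.atleast_2d(e.samples).shape
                  for e in clean_epochs + raw_epochs}
        if len(shapes) != 1:
            raise ValueError(f"segments have mixed shapes: {sorted(shapes)}")
        self.clean_epochs = clean_epochs
        self.raw_epochs = raw_epochs
        self._shape = shapes.pop()

    def fit(self, seed: int = 0) -> "MultimodalQualityResults":
        """Balance classes, extract summary features, train the classifier."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(seed)
        n = min(len(self.clean_epochs), len(self.raw_epochs))
        idx_c = rng.choice(len(self.clean_epochs), size=n, replace=False)
        idx_r = rng.choice(len(self.raw_epochs), size=n, replace=False)
        epochs = [self.clean_epochs[i] for i in idx_c] + \
                 [self.raw_epochs[i] for i in idx_r]
        X = np.vstack([_segment_features(e) for e in epochs])
        y = np.array([1] * n + [0] * n)  # {C: 1, R: 0}
        pipe = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=int(seed) % (2**31)),
        )
        pipe.fit(X, y)
        logger.info("trained reference classifier on %d balanced segments", 2 * n)
        return MultimodalQualityResults(pipe, self._shape)


class MultimodalQualityResults:
    """Trained segment classifier plus the Q_M scoring surface."""

    def __init__(self, classifier, segment_shape: tuple[int, int]):
        self.classifier = classifier
        self.segment_shape = segment_shape

    def predict_probabilities(self, epochs: list[Epoch]) -> pd.DataFrame:
        """(P_C, P_R) per segment from the trained classifier."""
        for e in epochs:
            if np.atleast_2d(e.samples).shape != self.segment_shape:
                raise ValueError(
                    f"segment shape {np.atleast_2d(e.samples).shape} does not "
                    f"match training shape {self.segment_shape}"
                )
        X = np.vstack([_segment_features(e) for e in epochs])
        proba = self.classifier.predict_proba(X)
        classes = list(self.classifier.classes_)
        return pd.DataFrame({
            "p_clean": proba[:, classes.index(1)],
            "p_raw": proba[:, classes.index(0)],
        })

    def score_segments(self, epochs: list[Epoch]) -> np.ndarray:
        """Q_M per multichannel segment."""
        probs = self.predict_probabilities(epochs)
        return np.array([
            score_multimodal(pc, pr)
            for pc, pr in zip(probs["p_clean"], probs["p_raw"])
        ])

    def accuracy(self, epochs: list[Epoch], labels: np.ndarray) -> float:
        """Hard-classification accuracy against {clean: 1, raw: 0} labels."""
        probs = self.predict_probabilities(epochs)
        pred = (probs["p_clean"].to_numpy() >= probs["p_raw"].to_numpy())
        return float(np.mean(pred.astype(int) == np.asarray(labels)))

    @staticmethod
    def score_probability_table(table: pd.DataFrame) -> pd.DataFrame:
        """Score an externally produced (epoch_id, p_clean, p_raw) table."""
        out = table.copy()
        out["score"] = [
            score_multimodal(pc, pr)
            for pc, pr in zip(table["p_clean"], table["p_raw"])
        ]
        return out

    def summary_by_class(self, epochs: list[Epoch], labels: np.ndarray
                         ) -> pd.DataFrame:
        """Mean +/- SD of probabilities and Q_M per labelled class."""
        probs = self.predict_probabilities(epochs)
        probs["score"] = [
            score_multimodal(pc, pr)
            for pc, pr in zip(probs["p_clean"], probs["p_raw"])
        ]
        probs["label"] = np.asarray(labels)
        rows = {}
        for label, grp in probs.groupby("label"):
            name = {1: "C", 0: "R"}.get(label, str(label))
            rows[name] = {
                "p_clean": grp["p_clean"].mean(),
                "p_raw": grp["p_raw"].mean(),
                "mean_score": grp["score"].mean(),
                "sd_score": grp["score"].std(ddof=1),
                "n": len(grp),
            }
        return pd.DataFrame(rows).T
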