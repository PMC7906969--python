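"""Unimodal signal-quality scoring from per-feature class densities.

The model is fitted to three labelled collections of feature vectors: clean
signal (C), raw recorded signal with the artifact present (R), and the
artifact source itself (N).  For every feature f it estimates Gaussian kernel
densities d_f for each class (Scott's-rule bandwidth), locates the equal-prior
Bayes decision critical value v_f* between the clean and noise densities, and
derives three error probabilities:

    P(error|C,f) = P( d_f(x|C) < d_f(x|N) | x in C )
    P(error|R,f) = P( d_f(x|C) < d_f(x|N) | x in R )
    P(error|N,f) = P( d_f(x|N) < d_f(x|C) | x in N )

An ideal feature separates C from N perfectly and splits R evenly, so its
deviation from the ideal profile is

    E_total,f = P(error|C,f) + |0.5 - P(error|R,f)| + P(error|N,f)

in [0, 2.5]; features with E_total,f at or below an inclusion threshold
(default 0.35) enter the score.  A recording's per-feature sub-score uses the
empirical class proportions around v_f* (when noise sits below clean):

    Q_f(v) = 1/2 + 1/2 P(v > x | x in C)   if v >= v_f*
           = 1/2 P(v <= x | x in N)        if v <  v_f*

with all inequalities mirrored when noise sits above clean, and the overall
score Q_U is the plain mean of Q_f over included features.  By construction
the mean score of clean data tends to 0.75, of pure noise to 0.25, and of an
even signal/noise mixture to 0.50; the aggregate deviation from those design
targets is

    delta = |0.75 - mean Q_U(C)| + |0.50 - mean Q_U(R)| + |0.25 - mean Q_U(N)|

Probabilities in the sub-score and error formulas are empirical proportions
over the stored fitting values; the KDEs enter only through the critical-value
search and the density comparisons above.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .features import FEATURE_NAMES
from .io import ClassLabel

logger = logging.getLogger(__name__)

__all__ = [
    "Density",
    "FeatureModel",
    "UnimodalQualityModel",
    "UnimodalQualityResults",
    "fit_density",
    "critical_value",
    "total_error",
    "feature_subscore",
    "delta_metric",
]

NOISE_BELOW = "noise_below_clean"
NOISE_ABOVE = "noise_above_clean"

#: key columns of feature tables that are not features
KEY_COLUMNS = ("subject", "channel", "epoch_start_s", "class")


class Density:
    """Univariate Gaussian KDE with Scott's-rule bandwidth.

    Wraps :class:`scipy.stats.gaussian_kde` fitted on ``support_samples``;
    callable as ``density(x)`` and exposing ``cdf(x)``.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if np.unique(values).size < 2:
            raise ValueError("KDE requires at least 2 distinct values")
        self.support_samples = values
        self._kde = gaussian_kde(values, bw_method="scott")

    @property
    def bandwidth(self) -> float:
        """Kernel standard deviation (Scott factor times the data SD)."""
        return float(np.sqrt(self._kde.covariance[0, 0]))

    def __call__(self, x) -> np.ndarray:
        return self._kde(np.atleast_1d(np.asarray(x, dtype=float)))

    def cdf(self, x: float) -> float:
        return float(self._kde.integrate_box_1d(-np.inf, x))


def fit_density(values: np.ndarray) -> Density:
    """Fit a Gaussian KDE (Scott's rule) to a vector of feature values."""
    return Density(values)


def critical_value(d_clean: Density, d_noise: Density) -> float:
    """Equal-prior Bayes decision threshold between two class densities.

    Searches a dense grid (2001 points) over the pooled hull of the two
    fitting samples for the single threshold minimising the equal-prior
    empirical misclassification rate, with the side assignment oriented by
    the class means.  Ties are broken toward the midpoint of the class means
    (which is itself a candidate, so fully degenerate overlap returns it
    exactly).
    """
    c = np.sort(d_clean.support_samples)
    n = np.sort(d_noise.support_samples)
    midpoint = 0.5 * (c.mean() + n.mean())
    lo = min(c[0], n[0])
    hi = max(c[-1], n[-1])
    grid = np.append(np.linspace(lo, hi, 2001), midpoint)
    frac_c_below = np.searchsorted(c, grid, side="left") / c.size
    frac_n_below = np.searchsorted(n, grid, side="left") / n.size
    if n.mean() <= c.mean():
        # classify v >= t as clean
        err = 0.5 * frac_c_below + 0.5 * (1.0 - frac_n_below)
    else:
        err = 0.5 * (1.0 - frac_c_below) + 0.5 * frac_n_below
    best = err.min()
    ties = np.flatnonzero(err <= best + 1e-12)
    return float(grid[ties[np.argmin(np.abs(grid[ties] - midpoint))]])


def total_error(err_clean: float, err_raw: float, err_noise: float) -> float:
    """E_total,f = P(error|C,f) + |0.5 - P(error|R,f)| + P(error|N,f)."""
    for p in (err_clean, err_raw, err_noise):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"error probability {p} outside [0, 1]")
    return err_clean + abs(0.5 - err_raw) + err_noise


def delta_metric(mean_clean: float, mean_raw: float, mean_noise: float) -> float:
    """Aggregate deviation of the three class mean scores from 0.75/0.50/0.25."""
    for q in (mean_clean, mean_raw, mean_noise):
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"mean score {q} outside [0, 1]")
    return abs(0.75 - mean_clean) + abs(0.50 - mean_raw) + abs(0.25 - mean_noise)


@dataclass
class FeatureModel:
    """Fitted per-feature model: class values, orientation, v*, errors.

    ``values_clean`` and ``values_noise`` are stored sorted ascending; the
    sub-score and the critical-value search use them as the empirical class
    distributions.  ``usable`` is False when a class had fewer than two
    distinct values (KDE undefined), in which case the feature is excluded
    from scoring regardless of the threshold.
    """

    feature_name: str
    values_clean: np.ndarray
    values_raw: np.ndarray
    values_noise: np.ndarray
    orientation: str = NOISE_BELOW
    critical_value: float = np.nan
    error_probs: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    e_total: float = np.nan
    usable: bool = True
    _densities: dict = field(default_factory=dict, repr=False)

    def density(self, label: ClassLabel) -> Density:
        label = ClassLabel(label)
        if label not in self._densities:
            values = {
                ClassLabel.CLEAN: self.values_clean,
                ClassLabel.RAW: self.values_raw,
                ClassLabel.NOISE: self.values_noise,
            }[label]
            self._densities[label] = fit_density(values)
        return self._densities[label]

    def subscores(self, values: np.ndarray) -> np.ndarray:
        """Vectorised Q_f over a vector of feature values."""
        v = np.atleast_1d(np.asarray(values, dtype=float))
        c = self.values_clean
        n = self.values_noise
        q = np.empty_like(v)
        if self.orientation == NOISE_BELOW:
            upper = v >= self.critical_value
            # P(v > x | x in C): proportion of clean values strictly below v
            q[upper] = 0.5 + 0.5 * (
                np.searchsorted(c, v[upper], side="left") / c.size
            )
            # P(v <= x | x in N): proportion of noise values at or above v
            q[~upper] = 0.5 * (
                (n.size - np.searchsorted(n, v[~upper], side="left")) / n.size
            )
        else:
            upper = v <= self.critical_value
            q[upper] = 0.5 + 0.5 * (
                (c.size - np.searchsorted(c, v[upper], side="right")) / c.size
            )
            q[~upper] = 0.5 * (
                np.searchsorted(n, v[~upper], side="right") / n.size
            )
        return q


def feature_subscore(value: float, fm: FeatureModel) -> float:
    """Per-feature sub-score Q_f(v) in [0, 1] (see module docstring)."""
    if not fm.usable or not np.isfinite(fm.critical_value):
        raise ValueError(f"feature model {fm.feature_name!r} is not fitted")
    return float(fm.subscores(np.array([value]))[0])


def _fit_feature(name: str, vc, vr, vn) -> FeatureModel:
    vc = np.sort(np.asarray(vc, dtype=float))
    vr = np.asarray(vr, dtype=float)
    vn = np.sort(np.asarray(vn, dtype=float))
    fm = FeatureModel(name, vc, vr, vn)
    if np.unique(vc).size < 2 or np.unique(vn).size < 2:
        warnings.warn(
            f"feature {name!r}: a class is (near-)constant; "
            "KDE undefined, feature excluded from scoring"
        )
        fm.usable = False
        return fm
    d_c = fm.density(ClassLabel.CLEAN)
    d_n = fm.density(ClassLabel.NOISE)
    fm.orientation = NOISE_BELOW if vn.mean() <= vc.mean() else NOISE_ABOVE
    fm.critical_value = critical_value(d_c, d_n)
    err_c = float(np.mean(d_c(vc) < d_n(vc)))
    err_r = float(np.mean(d_c(vr) < d_n(vr)))
    err_n = float(np.mean(d_n(vn) < d_c(vn)))
    fm.error_probs = (err_c, err_r, err_n)
    fm.e_total = total_error(err_c, err_r, err_n)
    return fm


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in KEY_COLUMNS]


class UnimodalQualityModel:
    """Signal-quality model built from clean / raw / noise feature tables.

    Parameters
    ----------
    clean, raw, noise
        Feature tables (`pandas.DataFrame`), one row per epoch.  Key columns
        (subject, channel, epoch_start_s, class) are ignored; every other
        column is treated as a feature.  All three tables must share the same
        feature columns.
    """

    def __init__(self, clean: pd.DataFrame, raw: pd.DataFrame,
                 noise: pd.DataFrame):
        self.tables = {
            ClassLabel.CLEAN: clean,
            ClassLabel.RAW: raw,
            ClassLabel.NOISE: noise,
        }
        for label, df in self.tables.items():
            if len(df) == 0:
                raise ValueError(f"empty feature table for class {label.value}")
        cols = _feature_columns(clean)
        for df in (raw, noise):
            if _feature_columns(df) != cols:
                raise ValueError("feature tables have mismatched columns")
        if not cols:
            raise ValueError("no feature columns found")
        self.feature_names = cols

    @classmethod
    def from_feature_tables(cls, clean_csv, raw_csv, noise_csv
                            ) -> "UnimodalQualityModel":
        """Build the model from three feature-table CSV files."""
        return cls(*(pd.read_csv(p) for p in (clean_csv, raw_csv, noise_csv)))

    def fit(self, inclusion_threshold: float = 0.35,
            min_samples: int = 10) -> "UnimodalQualityResults":
        """Fit per-feature class models and apply the E_total inclusion rule.

        ``min_samples`` is the per-class floor on fitting values per feature.
        """
        models: dict[str, FeatureModel] = {}
        for name in self.feature_names:
            vc = self.tables[ClassLabel.CLEAN][name].dropna().to_numpy()
            vr = self.tables[ClassLabel.RAW][name].dropna().to_numpy()
            vn = self.tables[ClassLabel.NOISE][name].dropna().to_numpy()
            for label, v in (("C", vc), ("R", vr), ("N", vn)):
                if v.size < min_samples:
                    raise ValueError(
                        f"feature {name!r}, class {label}: {v.size} samples "
                        f"< floor {min_samples}"
                    )
            models[name] = _fit_feature(name, vc, vr, vn)
        res = UnimodalQualityResults(
            feature_models=models,
            inclusion_threshold=inclusion_threshold,
            model=self,
        )
        if not res.included_features:
            warnings.warn(
                f"no feature has E_total <= {inclusion_threshold}; "
                "scoring will fail until the threshold is raised"
            )
        return res


class UnimodalQualityResults:
    """Fitted unimodal quality model: per-feature error table and scoring."""

    def __init__(self, feature_models: dict[str, FeatureModel],
                 inclusion_threshold: float,
                 model: UnimodalQualityModel | None = None):
        self.feature_models = feature_models
        self.inclusion_threshold = inclusion_threshold
        self.model = model

    # -- inclusion ---------------------------------------------------------

    def included_at(self, threshold: float) -> list[str]:
        return [
            name for name, fm in self.feature_models.items()
            if fm.usable and fm.e_total <= threshold
        ]

    @property
    def included_features(self) -> list[str]:
        return self.included_at(self.inclusion_threshold)

    # -- scoring -----------------------------------------------------------

    def subscores(self, table: pd.DataFrame,
                  features: list[str] | None = None) -> pd.DataFrame:
        """Per-feature Q_f for every row of a feature table."""
        if features is None:
            features = [n for n, fm in self.feature_models.items() if fm.usable]
        out = {}
        for name in features:
            fm = self.feature_models[name]
            out[name] = fm.subscores(table[name].to_numpy())
        return pd.DataFrame(out, index=table.index)

    def score(self, table: pd.DataFrame,
              threshold: float | None = None) -> np.ndarray:
        """Q_U for every row: mean of Q_f over the included features."""
        threshold = self.inclusion_threshold if threshold is None else threshold
        features = self.included_at(threshold)
        if not features:
            raise ValueError(
                f"no features meet E_total <= {threshold}; cannot score"
            )
        return self.subscores(table, features).to_numpy().mean(axis=1)

    def score_one(self, feature_vector: dict[str, float]) -> float:
        """Q_U of a single 30-entry feature vector."""
        return float(self.score(pd.DataFrame([feature_vector]))[0])

    # -- reporting ---------------------------------------------------------

    @property
    def error_table(self) -> pd.DataFrame:
        """Per-feature error probabilities and E_total, fitting order."""
        rows = []
        for name, fm in self.feature_models.items():
            ec, er, en = fm.error_probs
            rows.append({
                "feature": name,
                "P(error|C)": ec,
                "P(error|R)": er,
                "P(error|N)": en,
                "E_total": fm.e_total,
                "included": fm.usable and fm.e_total <= self.inclusion_threshold,
            })
        return pd.DataFrame(rows).set_index("feature")

    def class_summary(self, tables: dict, threshold: float | None = None
                      ) -> pd.DataFrame:
        """Mean +/- SD of Q_U per class, plus delta, for labelled tables.

        ``tables`` maps class labels ('C'/'R'/'N' or :class:`ClassLabel`) to
        feature tables.
        """
        rows = {}
        for label, df in tables.items():
            q = self.score(df, threshold)
            rows[ClassLabel(label).value] = {
                "mean": float(q.mean()), "sd": float(q.std(ddof=1)),
                "n": len(q),
            }
        out = pd.DataFrame(rows).T
        if set(rows) == {"C", "R", "N"}:
            out.attrs["delta"] = delta_metric(
                rows["C"]["mean"], rows["R"]["mean"], rows["N"]["mean"]
            )
        return out

    def sweep(self, tables: dict, grid: np.ndarray | None = None
              ) -> pd.DataFrame:
        """Class mean scores and delta across a grid of E_total thresholds.

        Sub-scores are computed once; each grid row just averages the subset
        of features admitted at that threshold.  The included-feature count is
        non-decreasing in the threshold.
        """
        if grid is None:
            grid = np.arange(0.0, 2.5001, 0.05)
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty threshold grid")
        sub = {
            ClassLabel(label).value: self.subscores(df)
            for label, df in tables.items()
        }
        rows = []
        for thr in grid:
            features = self.included_at(thr)
            row = {"threshold": float(thr), "n_features": len(features)}
            means = {}
            for label, s in sub.items():
                if features:
                    q = s[features].to_numpy().mean(axis=1)
                    row[f"mean_{label}"] = float(q.mean())
                    row[f"sd_{label}"] = float(q.std(ddof=1))
                    means[label] = row[f"mean_{label}"]
                else:
                    row[f"mean_{label}"] = np.nan
                    row[f"sd_{label}"] = np.nan
            if set(means) == {"C", "R", "N"}:
                row["delta"] = delta_metric(means["C"], means["R"], means["N"])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Statsmodels-style text summary of the fitted model."""
        lines = [
            "Unimodal signal-quality model",
            "=" * 64,
            f"features fitted:    {len(self.feature_models)}",
            f"inclusion rule:     E_total <= {self.inclusion_threshold}",
            f"features included:  {len(self.included_features)} "
            f"({', '.join(self.included_features) or 'none'})",
            "-" * 64,
            self.error_table.to_string(
                float_format=lambda v: f"{v:0.3f}", justify="right"
            ),
        ]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_sweep(self, sweep_df: pd.DataFrame, ax=None):
        """Plot class mean scores (with SD bands) and delta vs threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"C": "tab:green", "R": "tab:olive", "N": "tab:red"}
        for label, color in colors.items():
            ax.plot(sweep_df["threshold"], sweep_df[f"mean_{label}"],
                    color=color, label=f"mean Q_U({label})")
            ax.fill_between(
                sweep_df["threshold"],
                sweep_df[f"mean_{label}"] - sweep_df[f"sd_{label}"],
                sweep_df[f"mean_{label}"] + sweep_df[f"sd_{label}"],
                color=color, alpha=0.2,
            )
        if "delta" in sweep_df:
            ax.plot(sweep_df["threshold"], sweep_df["delta"], "k--",
                    label="delta")
        ax.set_xlabel("E_total threshold")
        ax.set_ylabel("score")
        ax.legend()
        return ax

    def plot_score_distributions(self, tables: dict, ax=None):
        """KDE curves of Q_U per class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(0, 1, 401)
        for label, df in tables.items():
            q = self.score(df)
            ax.plot(xs, fit_density(q)(xs), label=f"Q_U({ClassLabel(label).value})")
        ax.set_xlabel("Q_U")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the fitted model to a versioned JSON file.

        Stored floats round-trip exactly, so a reloaded model scores
        bit-identically to the in-memory one.
        """
        payload = {
            "format": "eegqual-unimodal-model",
            "version": 1,
            "inclusion_threshold": self.inclusion_threshold,
            "features": [
                {
                    "name": fm.feature_name,
                    "orientation": fm.orientation,
                    "critical_value": None
                    if not np.isfinite(fm.critical_value)
                    else fm.critical_value,
                    "error_probs": [None if not np.isfinite(p) else p
                                    for p in fm.error_probs],
                    "e_total": None if not np.isfinite(fm.e_total)
                    else fm.e_total,
                    "usable": fm.usable,
                    "values": {
                        "C": fm.values_clean.tolist(),
                        "R": fm.values_raw.tolist(),
                        "N": fm.values_noise.tolist(),
                    },
                }
                for fm in self.feature_models.values()
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "UnimodalQualityResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "eegqual-unimodal-model":
            raise ValueError(f"{path} is not a unimodal model file")
        models: dict[str, FeatureModel] = {}
        for item in payload["features"]:
            def _f(v):
                return np.nan if v is None else float(v)
            fm = FeatureModel(
                feature_name=item["name"],
                values_clean=np.asarray(item["values"]["C"], dtype=float),
                values_raw=np.asarray(item["values"]["R"], dtype=float),
                values_noise=np.asarray(item["values"]["N"], dtype=float),
                orientation=item["orientation"],
                critical_value=_f(item["critical_value"]),
                error_probs=tuple(_f(p) for p in item["error_probs"]),
                e_total=_f(item["e_total"]),
                usable=item["usable"],
            )
            models[fm.feature_name] = fm
        return cls(models, payload["inclusion_threshold"])
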