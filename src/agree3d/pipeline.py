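"""Study-level orchestration: quality-rating rules, pairwise comparison
enumeration, failure bookkeeping, median [IQR] summaries and rank-sum
group statistics.

Conventions (recorded in run provenance):

* final rating = round-half-up of the two-session mean; any session
  rating of 0 excludes the image;
* IQR is reported as a single width Q3 - Q1 with linear-interpolation
  quantiles;
* summaries pool all pairwise records within a group (per-image mean
  aggregation available via ``aggregate="per_image"``);
* rank-sum tests are exact for small tie-free samples, otherwise normal
  approximation with tie correction; Bonferroni factor 3 over the three
  rating-group pairings (and over the three rating strata for the
  ags-vs-manual per-stratum tests).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .metrics import AGS_VS_MANUAL, MANUAL_VS_MANUAL, PairwiseEvaluator

__all__ = [
    "QualityRating",
    "FailureLedger",
    "METRIC_COLUMNS",
    "finalize_ratings",
    "enumerate_manual_pairs",
    "enumerate_ags_pairs",
    "failure_report",
    "evaluate_image",
    "evaluate_cohort",
    "summarize",
    "rank_sum_test",
    "compare_groups",
    "compare_ags_to_manual",
]

METRIC_COLUMNS = ("dc_mm", "dsc", "mssd_mm", "um95_mm")
GROUPS = ("All Images", "Rating 1", "Rating 2", "Rating 3")


@dataclass(frozen=True)
class QualityRating:
    image_id: str
    session_ratings: tuple
    final_rating: int | None  # None when excluded

    @property
    def excluded(self) -> bool:
        return self.final_rating is None


@dataclass(frozen=True)
class FailureLedger:
    n_images: int
    n_observers: int
    n_attempts: int
    n_failures: int

    def __post_init__(self):
        if self.n_attempts != self.n_images * self.n_observers:
            raise ValidationError(
                f"attempts ({self.n_attempts}) != images x observers "
                f"({self.n_images} x {self.n_observers})"
            )

    @property
    def n_successes(self) -> int:
        return self.n_attempts - self.n_failures

    @property
    def failure_pct(self) -> float:
        return round(100.0 * self.n_failures / self.n_attempts, 1)

    @property
    def success_pct(self) -> float:
        return round(100.0 * self.n_successes / self.n_attempts, 1)

    def to_dict(self):
        return {
            "n_images": self.n_images,
            "n_observers": self.n_observers,
            "n_attempts": self.n_attempts,
            "n_failures": self.n_failures,
            "n_successes": self.n_successes,
            "failure_pct": self.failure_pct,
            "success_pct": self.success_pct,
        }


def final_rating(session_a: int, session_b: int) -> int | None:
    """Round-half-up mean of two session ratings; None if either is 0."""
    for s in (session_a, session_b):
        if s not in (0, 1, 2, 3):
            raise ValidationError(f"rating {s!r} outside the 0-3 scale")
    if session_a == 0 or session_b == 0:
        return None
    return int(np.floor((session_a + session_b) / 2.0 + 0.5))


def finalize_ratings(sessions) -> list[QualityRating]:
    """Apply exclusion and rounding rules to a two-session ratings table.

    ``sessions``: DataFrame with columns (image_id, session1, session2),
    or a mapping image_id -> (s1, s2).
    """
    if isinstance(sessions, pd.DataFrame):
        items = [
            (str(r.image_id), (int(r.session1), int(r.session2)))
            for r in sessions.itertuples()
        ]
    else:
        items = [(str(k), (int(v[0]), int(v[1]))) for k, v in sessions.items()]
    out = []
    for image_id, (s1, s2) in items:
        out.append(QualityRating(image_id, (s1, s2), final_rating(s1, s2)))
    return out


def retained_fraction(ratings: list[QualityRating]) -> float:
    """Percentage of images retained after exclusion, to one decimal."""
    if not ratings:
        raise ValidationError("empty ratings table")
    kept = sum(not r.excluded for r in ratings)
    return round(100.0 * kept / len(ratings), 1)


def enumerate_manual_pairs(contours) -> list[tuple]:
    """All ordered pairs of manual contours excluding self-pairs:
    n(n-1) pairs (12 for four observers)."""
    labels = list(contours)
    if len(labels) < 2:
        raise ValidationError("need at least 2 manual contours to pair")
    return [(a, b) for a, b in itertools.permutations(labels, 2)]


def enumerate_ags_pairs(ags, manual) -> list[tuple]:
    """Full cross product of successful ags contours x manual contours
    (16 for four of each).  Failed attempts contribute nothing."""
    return [(a, m) for a in list(ags) for m in list(manual)]


def failure_report(manifest) -> FailureLedger:
    """Count ags attempts/failures from a cohort manifest.

    Accepts a ``synthetic.Cohort`` or a manifest dict with an ``images``
    list whose entries carry ``ags`` attempt records with a ``status``
    of ``"success"`` or ``"failure"``.
    """
    attempts = failures = 0
    images = 0
    observers = None
    entries = _manifest_images(manifest)
    for entry in entries:
        images += 1
        ags = entry["ags"]
        if observers is None:
            observers = len(ags)
        elif observers != len(ags):
            raise ValidationError("inconsistent observer count across images")
        for att in ags:
            status = att.get("status")
            if status not in ("success", "failure"):
                raise ValidationError(
                    f"attempt {entry['image_id']}/{att.get('observer')} "
                    f"has no success/failure mark"
                )
            attempts += 1
            failures += status == "failure"
    if images == 0:
        raise ValidationError("manifest contains no images")
    return FailureLedger(images, observers or 0, attempts, failures)


def _manifest_images(manifest):
    if hasattr(manifest, "images") and hasattr(manifest, "config"):  # Cohort
        out = []
        for img in manifest.images:
            out.append(
                {
                    "image_id": img.image_id,
                    "ags": [
                        {
                            "observer": obs,
                            "status": "failure" if c is None else "success",
                        }
                        for obs, c in img.ags.items()
                    ],
                }
            )
        return out
    return manifest["images"]


# ---------------------------------------------------------------------------
# metric evaluation


def evaluate_image(manual: dict, ags: dict | None = None, *,
                   spacing: float = 1.0, coverage: float = 0.95,
                   image_id: str = "") -> list:
    """All pairwise AgreementRecords for one image.

    ``manual``: observer -> contour; ``ags``: observer -> contour or
    None (failed attempt).  Returns 12 manual records and up to 16
    ags-vs-manual records for four observers.
    """
    ags_ok = {f"{k}:ags": v for k, v in (ags or {}).items() if v is not None}
    man = {f"{k}:manual": v for k, v in manual.items()}
    ev = PairwiseEvaluator({**man, **ags_ok}, spacing=spacing,
                           coverage=coverage, image_id=image_id)
    records = [
        ev.record(a, b, MANUAL_VS_MANUAL)
        for a, b in enumerate_manual_pairs(man)
    ]
    if ags_ok:
        records += [
            ev.record(a, b, AGS_VS_MANUAL)
            for a, b in enumerate_ags_pairs(ags_ok, man)
        ]
    return records


def records_frame(records, ratings=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "source": r.source_label,
                "target": r.target_label,
                "kind": r.comparison_kind,
                "dc_mm": r.dc_mm,
                "dsc": r.dsc,
                "mssd_mm": r.mssd_mm,
                "um95_mm": r.um95_mm,
                "spacing_mm": r.spacing_mm,
            }
            for r in records
        ]
    )
    if ratings is not None and len(df):
        df["rating"] = df["image_id"].map(ratings).astype(int)
    return df


def evaluate_cohort(cohort, spacing: float = 1.0, coverage: float = 0.95,
                    with_ags: bool = True) -> pd.DataFrame:
    """Evaluate every retained image of an in-memory cohort; returns the
    records table with a ``rating`` column."""
    records, ratings = [], {}
    for img in cohort.images:
        ratings[img.image_id] = img.final_rating
        records += evaluate_image(
            img.manual, img.ags if with_ags else None,
            spacing=spacing, coverage=coverage, image_id=img.image_id,
        )
    df = records_frame(records, ratings)
    expected = sum(
        len(img.manual) * (len(img.manual) - 1)
        + (sum(c is not None for c in img.ags.values()) * len(img.manual)
           if with_ags else 0)
        for img in cohort.images
    )
    assert len(df) == expected, "pair-count conservation violated"
    return df


# ---------------------------------------------------------------------------
# summaries and statistics


def _iqr_width(x) -> float:
    q1, q3 = np.percentile(np.asarray(x, dtype=float), [25, 75])
    return float(q3 - q1)


def _group_frames(df: pd.DataFrame):
    yield "All Images", df
    if "rating" in df.columns:
        for r in (1, 2, 3):
            yield f"Rating {r}", df[df["rating"] == r]


def _aggregate(df: pd.DataFrame, metric: str, aggregate: str) -> np.ndarray:
    if aggregate == "per_image":
        return df.groupby("image_id")[metric].mean().to_numpy()
    return df[metric].to_numpy()


def summarize(records: pd.DataFrame, ratings: dict | None = None,
              aggregate: str = "pooled") -> pd.DataFrame:
    """Median [IQR width] per metric x group x comparison kind."""
    df = records.copy()
    if "rating" not in df.columns:
        if ratings is None:
            raise ValidationError("records lack ratings; pass a ratings map")
        df["rating"] = df["image_id"].map(ratings)
        if df["rating"].isna().any():
            missing = df.loc[df["rating"].isna(), "image_id"].unique()
            raise ValidationError(f"no final rating for image(s) {missing[:5]}")
    rows = []
    for kind, kdf in df.groupby("kind"):
        for group, gdf in _group_frames(kdf):
            if gdf.empty:
                continue
            for metric in METRIC_COLUMNS:
                vals = _aggregate(gdf, metric, aggregate)
                rows.append(
                    {
                        "metric": metric,
                        "group": group,
                        "kind": kind,
                        "median": float(np.median(vals)),
                        "iqr_width": _iqr_width(vals),
                        "n_pairs": int(len(gdf)),
                    }
                )
    return pd.DataFrame(rows)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution for small tie-free samples, otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("rank-sum test needs >= 2 values per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_groups(records: pd.DataFrame, kind: str = MANUAL_VS_MANUAL,
                   alpha: float = 0.05, aggregate: str = "pooled") -> pd.DataFrame:
    """Rank-sum tests between the three rating groups for each metric,
    Bonferroni-corrected by the 3 group pairings."""
    df = records[records["kind"] == kind]
    rows = []
    for metric in METRIC_COLUMNS:
        for ra, rb in ((1, 2), (1, 3), (2, 3)):
            ga = df[df["rating"] == ra]
            gb = df[df["rating"] == rb]
            row = {"metric": metric, "kind": kind,
                   "group_a": f"Rating {ra}", "group_b": f"Rating {rb}"}
            if len(ga) < 2 or len(gb) < 2:
                row.update(p_raw=np.nan, p_adjusted=np.nan,
                           significant=False, skipped=True)
            else:
                p = rank_sum_test(_aggregate(ga, metric, aggregate),
                                  _aggregate(gb, metric, aggregate))
                row.update(p_raw=p, p_adjusted=min(1.0, 3.0 * p),
                           significant=min(1.0, 3.0 * p) < alpha, skipped=False)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_ags_to_manual(records: pd.DataFrame, alpha: float = 0.05,
                          aggregate: str = "pooled") -> pd.DataFrame:
    """Rank-sum tests of ags-vs-manual records against manual-vs-manual
    records: uncorrected over all images, Bonferroni x3 over the three
    rating strata."""
    rows = []
    strata = [("All Images", records, 1.0)]
    strata += [
        (f"Rating {r}", records[records["rating"] == r], 3.0) for r in (1, 2, 3)
    ]
    for metric in METRIC_COLUMNS:
        for name, df, factor in strata:
            man = df[df["kind"] == MANUAL_VS_MANUAL]
            ags = df[df["kind"] == AGS_VS_MANUAL]
            row = {"metric": metric, "stratum": name}
            if len(man) < 2 or len(ags) < 2:
                row.update(p_raw=np.nan, p_adjusted=np.nan,
                           significant=False, skipped=True)
            else:
                p = rank_sum_test(_aggregate(ags, metric, aggregate),
                                  _aggregate(man, metric, aggregate))
                padj = min(1.0, factor * p)
                row.update(p_raw=p, p_adjusted=padj,
                           significant=padj < alpha, skipped=False)
            rows.append(row)
    return pd.DataFrame(rows)
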