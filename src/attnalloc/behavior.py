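"""Experiment-side attention statistics.

Two empirical estimates of how a supervisor divided attention among areas
of interest (AOIs) during a monitoring session:

* **Keypress attention** ``A_k``: each AOI produces overload events that
  demand a key response; the per-AOI correct-response ratio
  ``O_i = correct_i / overloads_i`` is treated as evidence of attention,
  and ``A_k = O / Σ O``.
* **Fixation attention** ``A_e``: the share of gaze fixations landing in
  each AOI, ``A_e = m / Σ m`` with ``m_i`` the fixation count.

Both are computed per participant (each participant's vector sums to one)
and then averaged for group reports. The module also provides the
model-vs-behavior statistics used to validate allocation predictions:
pairwise Pearson correlations of group-mean attention vectors across AOIs,
and one-sample t-tests of per-participant fractions against a model's
predicted fraction at a chosen AOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Model, allocate
from .profile import ValueProfile

__all__ = [
    "AOI",
    "FixationTable",
    "KeypressLog",
    "AttentionVector",
    "CorrelationEntry",
    "TTestEntry",
    "ComparisonReport",
    "keypress_attention",
    "fixation_attention",
    "correlation_matrix",
    "one_sample_ttest",
    "full_report",
]

FIXATION_COLUMNS = ["participant", "start_ms", "duration_ms", "x", "y"]
KEYPRESS_COLUMNS = ["participant", "time_ms", "aoi", "responded", "correct"]


@dataclass(frozen=True)
class AOI:
    """Axis-aligned screen rectangle, pixel coordinates, origin top-left.

    Half-open on the right and bottom edges (``x0 <= x < x1``,
    ``y0 <= y < y1``) so a point on a shared boundary belongs to exactly
    one AOI.
    """

    label: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"AOI {self.label!r}: degenerate rectangle")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def overlaps(self, other: "AOI") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass
class FixationTable:
    """Time-stamped gaze fixations, as exported by eye-tracking software.

    ``data`` columns: participant, start_ms, duration_ms, x, y. A
    pre-aggregated dialect (participant, aoi, count) is accepted via
    :meth:`from_counts`.
    """

    data: pd.DataFrame
    screen: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FIXATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"fixation table missing columns: {missing}")
        if (self.data["duration_ms"] <= 0).any():
            raise ValueError("fixation durations must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, screen: tuple[int, int] | None = None) -> "FixationTable":
        return cls(pd.read_csv(path), screen=screen)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, aois: Sequence[AOI]) -> "FixationTable":
        """Expand a (participant, aoi, count) table into synthetic fixations
        at AOI centers, so both dialects flow through one code path."""
        centers = {a.label: ((a.x0 + a.x1) / 2, (a.y0 + a.y1) / 2) for a in aois}
        rows = []
        for _, r in counts.iterrows():
            cx, cy = centers[r["aoi"]]
            for j in range(int(r["count"])):
                rows.append((r["participant"], j * 1000.0, 200.0, cx, cy))
        return cls(pd.DataFrame(rows, columns=FIXATION_COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.3f")

    def assign_aois(self, aois: Sequence[AOI]) -> pd.Series:
        """AOI label per fixation (NaN if outside all AOIs)."""
        x = self.data["x"].to_numpy(float)
        y = self.data["y"].to_numpy(float)
        out = pd.Series(pd.NA, index=self.data.index, dtype="object")
        for aoi in aois:
            inside = aoi.contains(x, y)
            out[inside & out.isna()] = aoi.label
        return out


@dataclass
class KeypressLog:
    """Overload events and the operator's responses.

    ``data`` columns: participant, time_ms, aoi, responded, correct.
    Each row is one overload event; ``correct`` implies ``responded``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KEYPRESS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"keypress log missing columns: {missing}")
        bad = self.data["correct"].astype(bool) & ~self.data["responded"].astype(bool)
        if bad.any():
            raise ValueError("correct responses must also be marked responded")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KeypressLog":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.3f")

    def per_aoi_totals(self) -> pd.DataFrame:
        """Overload and correct counts per participant and AOI."""
        g = self.data.groupby(["participant", "aoi"])
        out = g.agg(overloads=("aoi", "size"), correct=("correct", "sum"))
        return out.reset_index()


@dataclass(frozen=True)
class AttentionVector:
    """Group-level fractional attention with per-participant breakdown.

    ``fractions`` is the group mean across the participants retained in
    ``per_participant`` (rows indexed by participant, columns by AOI;
    each row sums to one).
    """

    source: str
    labels: tuple[str, ...]
    fractions: np.ndarray
    per_participant: pd.DataFrame | None = None
    sd: np.ndarray | None = None
    excluded: tuple = field(default_factory=tuple)

    @property
    def percent(self) -> np.ndarray:
        return self.fractions * 100.0


def keypress_attention(
    log: KeypressLog, labels: Sequence[str], pooled: bool = False
) -> AttentionVector:
    """Keypress-derived attention ``A_k = O / Σ O`` per participant.

    ``O_i`` is the correct-response ratio of AOI ``i``. A participant with
    any zero-overload AOI has an undefined ratio there and is excluded
    from the group mean. With ``pooled=True``, counts are pooled across
    participants before normalizing instead (non-default).
    """
    labels = tuple(labels)
    totals = log.per_aoi_totals()
    if totals.empty or totals["overloads"].sum() == 0:
        raise ValueError("keypress log contains no overload events")
    if pooled:
        agg = totals.groupby("aoi")[["overloads", "correct"]].sum().reindex(labels)
        if agg["overloads"].isna().any() or (agg["overloads"] == 0).any():
            raise ValueError("some AOI has no overload events in the pooled log")
        O = (agg["correct"] / agg["overloads"]).to_numpy(float)
        frac = O / O.sum()
        return AttentionVector("key", labels, frac)
    rows: dict = {}
    excluded = []
    for pid, sub in totals.groupby("participant"):
        sub = sub.set_index("aoi").reindex(labels)
        if sub["overloads"].isna().any() or (sub["overloads"] == 0).any():
            excluded.append(pid)
            continue
        O = (sub["correct"] / sub["overloads"]).to_numpy(float)
        if O.sum() == 0:
            excluded.append(pid)
            continue
        rows[pid] = O / O.sum()
    if not rows:
        raise ValueError("no participant has overload events in every AOI")
    pp = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    return AttentionVector(
        "key",
        labels,
        pp.mean(axis=0).to_numpy(),
        per_participant=pp,
        sd=pp.std(axis=0, ddof=1).to_numpy() if len(pp) > 1 else None,
        excluded=tuple(excluded),
    )


def fixation_attention(
    fixations: FixationTable,
    aois: Sequence[AOI],
    duration_weighted: bool = False,
) -> AttentionVector:
    """Fixation-derived attention ``A_e = m / Σ m`` per participant.

    ``m_i`` is the number of fixations inside AOI ``i`` (fixation counts;
    pass ``duration_weighted=True`` for dwell-time weighting instead).
    Fixations outside every AOI are dropped from the normalization.
    """
    labels = tuple(a.label for a in aois)
    for i, a in enumerate(aois):
        for b in aois[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"AOIs {a.label!r} and {b.label!r} overlap")
    df = fixations.data.copy()
    df["aoi"] = fixations.assign_aois(aois)
    df = df.dropna(subset=["aoi"])
    if df.empty:
        raise ValueError("no fixation falls inside any AOI")
    weight = df["duration_ms"] if duration_weighted else 1.0
    df = df.assign(w=weight)
    rows = {}
    for pid, sub in df.groupby("participant"):
        m = sub.groupby("aoi")["w"].sum().reindex(labels).fillna(0.0).to_numpy(float)
        rows[pid] = m / m.sum()
    pp = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    return AttentionVector(
        "eye",
        labels,
        pp.mean(axis=0).to_numpy(),
        per_participant=pp,
        sd=pp.std(axis=0, ddof=1).to_numpy() if len(pp) > 1 else None,
    )


@dataclass(frozen=True)
class CorrelationEntry:
    a: str
    b: str
    r: float
    p: float | None
    n: int


@dataclass(frozen=True)
class TTestEntry:
    """One-sample t-test of participant fractions against a model value."""

    sample: str
    aoi: str
    test_value: float
    n: int
    mean: float
    sd: float
    t: float | None
    df: int
    p: float | None
    mean_difference: float
    ci_low: float | None
    ci_high: float | None


@dataclass
class ComparisonReport:
    """Model-vs-behavior comparison: vectors, correlations, t-tests."""

    vectors: dict[str, AttentionVector]
    correlations: list[CorrelationEntry] = field(default_factory=list)
    ttests: list[TTestEntry] = field(default_factory=list)

    def correlation(self, a: str, b: str) -> CorrelationEntry:
        for e in self.correlations:
            if {e.a, e.b} == {a, b}:
                return e
        raise KeyError(f"no correlation entry for ({a}, {b})")

    def correlation_frame(self) -> pd.DataFrame:
        names = list(self.vectors)
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for e in self.correlations:
            mat.loc[e.a, e.b] = mat.loc[e.b, e.a] = e.r
        return mat

    def to_json(self, path: str | Path | None = None) -> str:
        import json

        payload = {
            "vectors": {
                k: {
                    "labels": list(v.labels),
                    "fractions": v.fractions.tolist(),
                    "sd": None if v.sd is None else v.sd.tolist(),
                    "n_participants": None
                    if v.per_participant is None
                    else int(len(v.per_participant)),
                    "excluded": list(v.excluded),
                }
                for k, v in self.vectors.items()
            },
            "correlations": [e.__dict__ for e in self.correlations],
            "ttests": [e.__dict__ for e in self.ttests],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def render(self) -> str:
        """Human-readable summary tables."""
        lines = ["Attention vectors (% per AOI)"]
        labels = next(iter(self.vectors.values())).labels
        lines.append("  " + "".join(f"{lab:>20}" for lab in ("source", *labels)))
        for name, v in self.vectors.items():
            vals = "".join(f"{x:20.2f}" for x in v.percent)
            lines.append("  " + f"{name:>20}" + vals)
        if self.correlations:
            lines.append("Pearson correlations")
            for e in self.correlations:
                p = "n/a" if e.p is None else f"{e.p:.3f}"
                lines.append(f"  r({e.a}, {e.b}) = {e.r:.3f}  (two-tailed p = {p})")
        if self.ttests:
            lines.append("One-sample t-tests")
            for t in self.ttests:
                tval = "undefined" if t.t is None else f"{t.t:.3f}"
                lines.append(
                    f"  {t.sample}@{t.aoi} vs {t.test_value:.4f}: t = {tval}, "
                    f"df = {t.df}, mean diff = {t.mean_difference:+.5f}"
                )
        return "\n".join(lines)


def correlation_matrix(vectors: Mapping[str, AttentionVector]) -> list[CorrelationEntry]:
    """Pairwise Pearson r of group-mean attention vectors across AOIs.

    Two-tailed p comes from the t-transform with ``df = n − 2`` where ``n``
    is the number of AOIs. A zero-variance vector has undefined r, reported
    as NaN with ``p=None``.
    """
    names = list(vectors)
    if len(names) < 2:
        raise ValueError("need at least two vectors")
    lengths = {len(vectors[k].fractions) for k in names}
    if len(lengths) != 1 or lengths.pop() < 3:
        raise ValueError("vectors must share a common length of at least 3")
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x = vectors[a].fractions
            y = vectors[b].fractions
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                out.append(CorrelationEntry(a, b, float("nan"), None, len(x)))
                continue
            res = stats.pearsonr(x, y)
            out.append(CorrelationEntry(a, b, float(res.statistic), float(res.pvalue), len(x)))
    return out


def one_sample_ttest(
    sample: Sequence[float], test_value: float, sample_name: str = "sample", aoi: str = ""
) -> TTestEntry:
    """One-sample t-test of per-participant fractions against a model value.

    Returns ``t = (mean − test_value) / (sd / √n)`` with ``df = n − 1``, the
    two-tailed p, the mean difference, and the 95% CI of the difference.
    Zero sample variance leaves t undefined (reported as None).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if not (0.0 <= test_value <= 1.0):
        raise ValueError("test value must be a fraction in [0, 1]")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    n = x.size
    diff = mean - test_value
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return TTestEntry(
            sample_name, aoi, test_value, n, mean, sd, None, n - 1, None, diff, None, None
        )
    res = stats.ttest_1samp(x, popmean=test_value)
    ci = res.confidence_interval(0.95)
    return TTestEntry(
        sample=sample_name,
        aoi=aoi,
        test_value=float(test_value),
        n=n,
        mean=mean,
        sd=sd,
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        mean_difference=diff,
        ci_low=float(ci.low - test_value),
        ci_high=float(ci.high - test_value),
    )


def full_report(
    profile: ValueProfile,
    fixations: FixationTable | None = None,
    keylog: KeypressLog | None = None,
    aois: Sequence[AOI] | None = None,
    ttest_aois: Sequence[str] | None = None,
) -> ComparisonReport:
    """Assemble the model-vs-behavior comparison.

    Always includes both theoretical vectors; adds the fixation- and
    keypress-derived vectors when the corresponding inputs are given, the
    full pairwise correlation matrix, and one-sample t-tests of each
    empirical source against both models' predictions at ``ttest_aois``
    (default: the two highest-importance AOIs).
    """
    labels = profile.labels
    if aois is not None:
        aoi_labels = tuple(a.label for a in aois)
        if set(aoi_labels) != set(labels):
            raise ValueError(
                f"AOI labels {sorted(set(aoi_labels) - set(labels))} do not match "
                f"profile labels {sorted(set(labels) - set(aoi_labels))}"
            )
    prop = allocate(profile, Model.PROPOSED)
    mats = allocate(profile, Model.MATSUI)
    vectors: dict[str, AttentionVector] = {
        "model_matsui": AttentionVector("model_matsui", labels, mats.A),
        "model_proposed": AttentionVector("model_proposed", labels, prop.A),
    }
    if keylog is not None and len(keylog):
        key_labels = labels
        extra = set(keylog.data["aoi"].unique()) - set(labels)
        if extra:
            raise ValueError(f"keypress log has unknown AOI labels: {sorted(extra)}")
        vectors["key"] = keypress_attention(keylog, key_labels)
    if fixations is not None:
        if aois is None:
            raise ValueError("fixation analysis requires AOI rectangles")
        ordered = sorted(aois, key=lambda a: labels.index(a.label))
        vectors["eye"] = fixation_attention(fixations, ordered)

    report = ComparisonReport(vectors=vectors)
    report.correlations = correlation_matrix(vectors)

    if ttest_aois is None:
        order = np.argsort(profile.V)
        ttest_aois = [labels[i] for i in order[-2:]]
    for src in ("eye", "key"):
        v = vectors.get(src)
        if v is None or v.per_participant is None or len(v.per_participant) < 2:
            continue
        for model_name, result in (("model_proposed", prop), ("model_matsui", mats)):
            for lab in ttest_aois:
                j = labels.index(lab)
                report.ttests.append(
                    one_sample_ttest(
                        v.per_participant[lab].to_numpy(),
                        float(result.A[j]),
                        sample_name=f"{src}_vs_{model_name}",
                        aoi=lab,
                    )
                )
    return report
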