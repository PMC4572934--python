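"""Normalization, Manhattan-distance scoring, p-values, and hit calling.

The screen's readout is the firefly/renilla ratio (RLU). Within each
(plate, replicate), RLUs are normalized to the mean RLU of that plate's
TNFa control wells, so an activity of 1 means "indistinguishable from the
induced control". Each compound's hit statistic is the Manhattan (L1)
distance between its replicate activity vector and the all-ones control
mean. Distances are converted to p-values against a null distribution
built from the TNFa control wells of the same library plate, either
empirically (add-one upper-tail rank) or by a half-normal fit. Hits must
be significant, inhibitory (mean activity < 1), and pass a renilla
viability filter that removes cytotoxic or poorly transfected compounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .plate_model import ScreenDataset

__all__ = [
    "UndefinedRLUError",
    "NullModel",
    "FlowchartReport",
    "HitCaller",
    "compute_rlu",
    "normalize_plate",
    "score_compound",
    "build_null",
    "p_value",
    "viability_filter",
    "select_hits",
    "z_prime_factor",
]

SCORE_COLUMNS = [
    "compound_id",
    "plate_id",
    "n_replicates",
    "mean_activity",
    "distance",
    "p_value",
    "inhibits",
    "renilla_ok",
    "significant",
    "hit",
]


class UndefinedRLUError(ValueError):
    """Raised when a reporter ratio is requested for a zero-renilla well."""

    def __init__(self, message: str, well: tuple | None = None):
        super().__init__(message)
        self.well = well


class DegenerateNullError(ValueError):
    """Raised when every control distance is zero (no noise to calibrate on)."""


def compute_rlu(firefly: float, renilla: float) -> float:
    """Reporter ratio firefly / renilla for one well.

    Raises
    ------
    UndefinedRLUError
        If ``renilla == 0``; callers route such wells to the
        viability-excluded set rather than dropping them silently.
    """
    if renilla == 0:
        raise UndefinedRLUError("RLU undefined: renilla is 0")
    return firefly / renilla


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize the wells of one (plate, replicate) to its TNFa mean.

    Adds ``rlu`` (firefly/renilla; NaN where renilla is 0) and
    ``normalized_activity`` (rlu over the mean rlu of the TNFa wells of
    this plate-replicate). By construction, the mean normalized activity
    of the TNFa wells is exactly 1.

    Raises
    ------
    ValueError
        If the group spans multiple plate-replicates or has no TNFa well
        with a defined ratio.
    """
    key = wells[["plate_id", "replicate"]].drop_duplicates()
    if len(key) != 1:
        raise ValueError("normalize_plate expects one (plate_id, replicate) group")
    out = wells.copy()
    renilla = out["renilla"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rlu = np.where(renilla > 0, out["firefly"].to_numpy(dtype=float) / renilla,
                       np.nan)
    out["rlu"] = rlu
    tnfa = out.loc[(out["role"] == "TNFA") & np.isfinite(out["rlu"]), "rlu"]
    if tnfa.empty:
        plate, rep = key.iloc[0]
        raise ValueError(
            f"plate {plate} replicate {rep}: no TNFA control well with a "
            "defined RLU; cannot normalize"
        )
    out["normalized_activity"] = out["rlu"] / tnfa.mean()
    return out


def score_compound(replicate_activities) -> float:
    """Manhattan distance of a replicate activity vector from the control mean.

    After normalization the control mean is 1 in every replicate, so the
    statistic is ``sum_r |activity_r - 1|``. Missing replicates (NaN) are
    ignored; an empty vector is an error.
    """
    a = np.asarray(replicate_activities, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no replicate activities to score")
    return float(np.abs(a - 1.0).sum())


@dataclass
class NullModel:
    """Null distribution of distance scores for one library plate.

    ``EMPIRICAL`` keeps the sorted control distances and uses the add-one
    upper-tail rank estimator; ``HALF_NORMAL`` summarizes them by the
    root-mean-square scale of a half-normal.
    """

    plate_id: str
    method: str  # "empirical" | "half_normal"
    null_distances: np.ndarray = field(repr=False)
    n_replicates: int = 0

    def __post_init__(self):
        self.null_distances = np.sort(np.asarray(self.null_distances, float))
        if self.method not in ("empirical", "half_normal"):
            raise ValueError(f"unknown null method {self.method!r}")
        if np.allclose(self.null_distances, 0.0):
            raise DegenerateNullError(
                f"plate {self.plate_id}: all control distances are zero"
            )

    @property
    def n(self) -> int:
        return self.null_distances.size

    @property
    def sigma(self) -> float:
        """Half-normal scale: sqrt(mean of squared null distances)."""
        return float(np.sqrt(np.mean(self.null_distances**2)))


def build_null(control_activities: pd.DataFrame, method: str = "empirical",
               plate_id: str = "") -> NullModel:
    """Build a plate's null model from its TNFa control wells.

    Parameters
    ----------
    control_activities : pandas.DataFrame
        One row per (control well, replicate) with columns ``row, col,
        replicate, normalized_activity``; each well position contributes
        one null distance, scored over its replicates exactly as a
        compound would be.
    method : {"empirical", "half_normal"}
    """
    min_wells = 3 if method == "empirical" else 2
    keys = [c for c in ("plate_id", "row", "col")
            if c in control_activities.columns]
    grouped = control_activities.groupby(keys)["normalized_activity"]
    distances = grouped.apply(lambda a: score_compound(a.to_numpy()))
    if distances.size < min_wells:
        raise ValueError(
            f"plate {plate_id or '?'}: {distances.size} control wells is "
            f"too few for a {method} null (need >= {min_wells})"
        )
    n_rep = int(grouped.size().max())
    return NullModel(plate_id, method, distances.to_numpy(), n_rep)


def p_value(distance: float, null: NullModel) -> float:
    """Upper-tail probability of a distance at least this large under the null.

    EMPIRICAL: ``p = (#{null >= d} + 1) / (n + 1)`` -- the add-one
    permutation-style estimator, never exactly 0. HALF_NORMAL:
    ``p = 2 (1 - Phi(d / sigma))``.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if null.method == "empirical":
        n_ge = null.n - np.searchsorted(null.null_distances, distance, "left")
        return float((n_ge + 1) / (null.n + 1))
    return float(2.0 * stats.norm.sf(distance / null.sigma))


def viability_filter(compound_renilla, plate_renilla_median: float,
                     threshold: float = 0.5) -> bool:
    """Whether a compound's renilla signal is compatible with viable cells.

    Retained iff the median of the compound's renilla values across
    replicates is at least ``threshold`` times the plate renilla median
    (boundary inclusive). Low renilla indicates cytotoxicity or poor
    transfection.
    """
    if plate_renilla_median <= 0:
        raise ValueError("plate renilla median must be > 0")
    med = float(np.median(np.asarray(compound_renilla, dtype=float)))
    return med >= threshold * plate_renilla_median


@dataclass
class FlowchartReport:
    """Staged accounting of compounds surviving each hit-selection filter."""

    n_tested: int
    n_significant: int
    n_removed_by_direction: int
    n_removed_by_viability: int
    n_hits: int
    alpha: float
    viability_threshold: float

    def __post_init__(self):
        assert self.n_hits == (
            self.n_significant
            - self.n_removed_by_direction
            - self.n_removed_by_viability
        ), "flowchart counts are inconsistent"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


class HitCaller(BaseEstimator):
    """Hit selection for a dual-luciferase reporter screen.

    Fitting normalizes every plate-replicate to its TNFa control mean,
    scores each library compound by the L1 distance of its replicate
    activity vector from the control mean, converts distances to p-values
    against the plate's control-derived null, and applies -- in order --
    the significance (p <= alpha), direction (mean activity < 1), and
    renilla viability filters.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level on the (optionally adjusted) p-value.
    null_method : {"empirical", "half_normal"}, default "empirical"
        Empirical makes no distributional claim and never returns p = 0;
        half-normal is a parametric alternative for small control pools.
    viability_threshold : float, default 0.5
        A compound is viable if its median renilla is at least this
        fraction of the plate renilla median.
    pool_plates : bool, default False
        Pool null distances across library plates instead of the default
        per-plate null.
    bh : bool, default False
        Apply Benjamini-Hochberg adjustment before thresholding at alpha.

    Attributes
    ----------
    scores_ : pandas.DataFrame
        One row per library compound (columns ``SCORE_COLUMNS``).
    flowchart_ : FlowchartReport
        Stage counts of the selection funnel.
    null_models_ : dict
        ``plate_id -> NullModel`` (full-replicate nulls).
    normalized_ : pandas.DataFrame
        All wells with ``rlu`` and ``normalized_activity`` columns.
    """

    def __init__(self, alpha: float = 0.05, null_method: str = "empirical",
                 viability_threshold: float = 0.5, pool_plates: bool = False,
                 bh: bool = False):
        self.alpha = alpha
        self.null_method = null_method
        self.viability_threshold = viability_threshold
        self.pool_plates = pool_plates
        self.bh = bh

    def fit(self, dataset: ScreenDataset, y=None) -> "HitCaller":
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        dataset.validate()
        normalized = pd.concat(
            [
                normalize_plate(grp)
                for _, grp in dataset.wells.groupby(
                    ["plate_id", "replicate"], sort=True
                )
            ],
            ignore_index=True,
        )
        self.normalized_ = normalized

        # per-plate null pools keyed by the set of replicates a compound has;
        # compounds with missing replicates are judged against a null of
        # matching dimensionality
        tnfa = normalized[normalized["role"] == "TNFA"]
        null_cache: dict[tuple[str, tuple[int, ...]], NullModel] = {}

        def null_for(plate_id: str, reps: tuple[int, ...]) -> NullModel:
            key = ("*" if self.pool_plates else plate_id, reps)
            if key not in null_cache:
                sub = tnfa if self.pool_plates else tnfa[tnfa["plate_id"] == plate_id]
                sub = sub[sub["replicate"].isin(reps)]
                null_cache[key] = build_null(
                    sub, self.null_method, plate_id=key[0]
                )
            return null_cache[key]

        lib = normalized[normalized["role"] == "LIBRARY"]
        plate_renilla_median = dataset.wells.groupby("plate_id")["renilla"].median()

        records = []
        for (cid, plate_id), grp in lib.groupby(["compound_id", "plate_id"],
                                                sort=True):
            act = grp.loc[np.isfinite(grp["normalized_activity"]),
                          ["replicate", "normalized_activity"]]
            if act.empty:
                # all replicates undefined (renilla 0): excluded by viability
                records.append(
                    dict(compound_id=cid, plate_id=plate_id, n_replicates=0,
                         mean_activity=np.nan, distance=np.nan, p_value=np.nan,
                         inhibits=False, renilla_ok=False, significant=False)
                )
                continue
            reps = tuple(sorted(act["replicate"]))
            activities = act["normalized_activity"].to_numpy()
            d = score_compound(activities)
            p = p_value(d, null_for(plate_id, reps))
            records.append(
                dict(
                    compound_id=cid,
                    plate_id=plate_id,
                    n_replicates=len(reps),
                    mean_activity=float(activities.mean()),
                    distance=d,
                    p_value=p,
                    inhibits=bool(activities.mean() < 1.0),
                    renilla_ok=viability_filter(
                        grp["renilla"].to_numpy(),
                        float(plate_renilla_median[plate_id]),
                        self.viability_threshold,
                    ),
                    significant=False,
                )
            )
        scores = pd.DataFrame.from_records(records)

        pvals = scores["p_value"].to_numpy()
        if self.bh:
            adjusted = np.full_like(pvals, np.nan)
            ok = np.isfinite(pvals)
            adjusted[ok] = stats.false_discovery_control(pvals[ok], method="bh")
            scores["p_adjusted"] = adjusted
            scores["significant"] = adjusted <= self.alpha
        else:
            scores["significant"] = pvals <= self.alpha
        scores["hit"] = (
            scores["significant"] & scores["inhibits"] & scores["renilla_ok"]
        )

        n_sig = int(scores["significant"].sum())
        n_dir = int((scores["significant"] & ~scores["inhibits"]).sum())
        n_via = int(
            (scores["significant"] & scores["inhibits"] & ~scores["renilla_ok"]).sum()
        )
        self.flowchart_ = FlowchartReport(
            n_tested=len(scores),
            n_significant=n_sig,
            n_removed_by_direction=n_dir,
            n_removed_by_viability=n_via,
            n_hits=int(scores["hit"].sum()),
            alpha=self.alpha,
            viability_threshold=self.viability_threshold,
        )
        full_reps = {
            pid: tuple(sorted(dataset.replicates(pid))) for pid in dataset.plate_ids
        }
        self.null_models_ = {
            pid: null_for(pid, reps) for pid, reps in full_reps.items()
        }
        cols = SCORE_COLUMNS + (["p_adjusted"] if self.bh else [])
        self.scores_ = scores[cols].reset_index(drop=True)
        return self

    def predict(self, dataset: ScreenDataset | None = None) -> pd.Series:
        """Hit call per compound from the fitted screen."""
        if dataset is not None:
            self.fit(dataset)
        return self.scores_.set_index("compound_id")["hit"]


def select_hits(
    dataset: ScreenDataset,
    alpha: float = 0.05,
    null_method: str = "empirical",
    viability_threshold: float = 0.5,
    **kwargs,
) -> tuple[pd.DataFrame, FlowchartReport]:
    """Run the full hit-selection chain on a screen.

    Thin functional wrapper over :class:`HitCaller`; returns the
    per-compound score table and the flowchart report.
    """
    caller = HitCaller(
        alpha=alpha,
        null_method=null_method,
        viability_threshold=viability_threshold,
        **kwargs,
    ).fit(dataset)
    return caller.scores_, caller.flowchart_


def z_prime_factor(normalized: pd.DataFrame, positive: str = "TNFA",
                   negative: str = "DMSO") -> float:
    """Z'-factor assay-quality metric between two control roles.

    ``1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|`` on RLU values;
    reported as QC only, never used to gate hits.
    """
    pos = normalized.loc[normalized["role"] == positive, "rlu"]
    neg = normalized.loc[normalized["role"] == negative, "rlu"]
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return -np.inf
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)
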