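"""Behavioural-feature derivation and predictor preprocessing.

Covers the trait derivations (body condition, fall orientation and timing
from detection streams) and the model-ready preprocessing chain: Pearson
correlation pruning at |r| >= 0.7, the 25 % missingness filter with a
behavioural whitelist, z-standardization, k-nearest-neighbour imputation
(nan-Euclidean distances, uniform weights, k = 5) and an 80/20 stratified
split.

Two pipeline orders are exposed.  ``paper-literal`` (default) standardizes
and imputes the full table before splitting; ``strict`` fits the
standardizer and imputer on training rows only and applies them to the test
rows, trading fidelity for leakage hygiene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "FEATURE_PANEL",
    "body_condition",
    "great_circle_km",
    "initial_bearing",
    "fall_bearing",
    "fall_timing",
    "correlation_prune",
    "missingness_filter",
    "Standardizer",
    "knn_impute",
    "stratified_split",
    "build_feature_matrix",
    "prepare_features",
]

#: The 14-feature predictor panel retained after pruning and filtering.
FEATURE_PANEL = (
    "distal", "p10", "condition", "tarsus", "kipps", "tail", "wing_chord",
    "fall_timing", "fall_bearing", "release_day", "release_year",
    "ancestry", "heterozygosity", "sex",
)

#: Candidate features before redundancy pruning.
CANDIDATE_FEATURES = (
    "wing_chord", "kipps", "distal", "p7", "p8", "p9", "p10", "tail",
    "tarsus", "weight", "condition", "fall_timing", "fall_bearing",
    "release_day", "release_year", "ancestry", "heterozygosity", "sex",
)

#: Ordered keep-priority for correlated pairs: earlier names win.
DEFAULT_PRUNE_PRIORITY = (
    "wing_chord", "condition", "tarsus", "kipps", "distal", "tail", "p10",
    "ancestry", "heterozygosity", "fall_bearing", "fall_timing",
    "release_day", "release_year", "sex",
)

#: Behavioural features kept despite ~28 % missingness.
MISSINGNESS_WHITELIST = ("fall_timing", "fall_bearing")

_EARTH_KM = 6371.0


def body_condition(weight, tarsus):
    """Weight over tarsus length (g/mm), a proxy for energy stores."""
    if weight is None or tarsus is None:
        return math.nan
    weight = float(weight)
    tarsus = float(tarsus)
    if math.isnan(weight) or math.isnan(tarsus):
        return math.nan
    if tarsus <= 0:
        raise ValueError(f"tarsus length must be positive, got {tarsus}")
    return weight / tarsus


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance (km, spherical Earth R = 6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * _EARTH_KM * math.asin(min(1.0, math.sqrt(a)))


def initial_bearing(lat1, lon1, lat2, lon2) -> float:
    """Initial great-circle bearing, compass degrees clockwise from north."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlam = math.radians(lon2 - lon1)
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    theta = math.degrees(math.atan2(y, x)) % 360.0
    return 0.0 if theta == 360.0 else theta  # fold the rounding artifact at 2*pi


def _doy(release_day: float, days_since_tag: float) -> float:
    return release_day + days_since_tag


def fall_bearing(
    release,
    detections: pd.DataFrame,
    max_km: float = 300.0,
    release_day: float | None = None,
    fall_window: tuple = (213.0, 304.0),
) -> float:
    """Fall orientation: bearing from the release site to the first station
    detected within ``max_km``; NaN if no detection qualifies.

    Stations coincident with the release site are skipped (bearing undefined
    at zero distance).  When ``release_day`` is given, only detections whose
    day-of-year falls inside ``fall_window`` are considered, so the trait
    reflects the start of fall migration rather than a spring return.
    """
    lat0, lon0 = release
    det = detections.sort_values("days_since_tag")
    for _, row in det.iterrows():
        if release_day is not None:
            doy = _doy(release_day, row["days_since_tag"])
            if not (fall_window[0] <= doy <= fall_window[1]):
                continue
        d = great_circle_km(lat0, lon0, row["lat"], row["lon"])
        if d <= 0.0 or d > max_km:
            continue
        return initial_bearing(lat0, lon0, row["lat"], row["lon"])
    return math.nan


def fall_timing(
    release_day: float,
    release,
    detections: pd.DataFrame,
    max_km: float = 30.0,
    fall_window: tuple = (213.0, 304.0),
) -> float:
    """Day-of-year of the first detection within ``max_km`` of the release
    site during the fall window; NaN if none."""
    lat0, lon0 = release
    det = detections.sort_values("days_since_tag")
    for _, row in det.iterrows():
        doy = _doy(release_day, row["days_since_tag"])
        if not (fall_window[0] <= doy <= fall_window[1]):
            continue
        if great_circle_km(lat0, lon0, row["lat"], row["lon"]) <= max_km:
            return float(doy)
    return math.nan


def correlation_prune(table: pd.DataFrame, threshold: float = 0.7, priority=DEFAULT_PRUNE_PRIORITY):
    """Drop one member of every feature pair with |Pearson r| >= threshold.

    Pairs are scanned in descending |r| (complete pairwise observations);
    within a pair the member absent from — or later in — the priority
    keep-list is dropped.  Returns the retained feature names in input order.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two features to prune")
    corr = table.corr(method="pearson").to_numpy()
    rank = {name: i for i, name in enumerate(priority)}
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr[i, j]
            if not math.isnan(r) and abs(r) >= threshold:
                pairs.append((abs(r), cols[i], cols[j]))
    pairs.sort(key=lambda t: -t[0])
    dropped: set = set()
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        ra = rank.get(a, len(priority))
        rb = rank.get(b, len(priority))
        dropped.add(b if ra <= rb else a)
    kept = [c for c in cols if c not in dropped]
    if not kept:
        warnings.warn("all features mutually correlated; keeping one")
        kept = [cols[0]]
    return kept


def missingness_filter(table: pd.DataFrame, max_frac: float = 0.25, whitelist=MISSINGNESS_WHITELIST):
    """Retain features whose missing fraction is <= max_frac (strict
    exclusion above it), plus whitelisted features regardless."""
    kept = []
    for col in table.columns:
        frac = float(table[col].isna().mean())
        if frac <= max_frac or col in whitelist:
            kept.append(col)
    return kept


@dataclass
class Standardizer:
    """(x - mean) / sd per feature; parameters fitted once and reusable on
    held-out rows (no-leakage contract in strict mode)."""

    means: pd.Series = field(default=None)
    sds: pd.Series = field(default=None)

    def fit(self, table: pd.DataFrame) -> "Standardizer":
        self.means = table.mean(skipna=True)
        self.sds = table.std(skipna=True, ddof=0)
        zero = self.sds[self.sds == 0]
        if len(zero):
            raise ValueError(f"zero-variance feature(s): {list(zero.index)}")
        if self.sds.isna().any():
            bad = list(self.sds[self.sds.isna()].index)
            raise ValueError(f"feature(s) with no observed values: {bad}")
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table - self.means) / self.sds

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def knn_impute(table: pd.DataFrame, k: int = 5, fit_table: pd.DataFrame | None = None):
    """KNN imputation: each missing cell becomes the unweighted mean of the
    feature among the k rows nearest under the nan-Euclidean distance
    sqrt(n_features / n_observed_pairs * sum of squared differences over
    co-observed features).

    Returns (completed table, provenance mask) where the mask is True at
    imputed cells.  ``fit_table`` supplies the neighbour pool (strict mode
    fits on training rows only).
    """
    for col in table.columns:
        if table[col].isna().all() and (fit_table is None or fit_table[col].isna().all()):
            raise ValueError(f"feature {col!r} has no observed values")
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    if fit_table is None:
        completed = imputer.fit_transform(table.to_numpy(dtype=float))
    else:
        imputer.fit(fit_table.to_numpy(dtype=float))
        completed = imputer.transform(table.to_numpy(dtype=float))
    out = pd.DataFrame(completed, index=table.index, columns=table.columns)
    provenance = table.isna()
    return out, provenance


def stratified_split(labels, test_frac: float = 0.2, seed: int = 0):
    """Per-class random 80/20 partition; deterministic under the seed.

    Returns (train_idx, test_idx) as integer positions.  Class proportions
    are preserved to within one sample per class.
    """
    labels = np.asarray(labels)
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_test = int(round(test_frac * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.sort(np.concatenate(test))
    return train_idx, test_idx


def build_feature_matrix(
    traits: pd.DataFrame,
    detections: pd.DataFrame | None = None,
    fall_window: tuple = (213.0, 304.0),
) -> pd.DataFrame:
    """Assemble the candidate predictor table (one row per bird).

    Body condition is derived from weight and tarsus.  Fall bearing and
    timing are taken from the trait table when present, otherwise derived
    from the detection stream.
    """
    df = traits.set_index("bird_id")
    out = pd.DataFrame(index=df.index)
    for col in ("wing_chord", "kipps", "distal", "p7", "p8", "p9", "p10",
                "tail", "tarsus", "weight", "release_day", "release_year",
                "ancestry", "heterozygosity", "sex"):
        out[col] = pd.to_numeric(df[col], errors="coerce")
    out["condition"] = [
        body_condition(w, t) if (pd.notna(t) and t > 0) else math.nan
        for w, t in zip(out["weight"], out["tarsus"])
    ]
    have_behaviour = "fall_bearing" in df.columns and "fall_timing" in df.columns
    if have_behaviour:
        out["fall_bearing"] = pd.to_numeric(df["fall_bearing"], errors="coerce")
        out["fall_timing"] = pd.to_numeric(df["fall_timing"], errors="coerce")
    else:
        if detections is None:
            raise ValueError("need detections to derive fall bearing/timing")
        bearings, timings = [], []
        groups = dict(tuple(detections.groupby("bird_id")))
        empty = detections.iloc[0:0]
        for bid in out.index:
            det = groups.get(bid, empty)
            release = (df.loc[bid, "release_lat"], df.loc[bid, "release_lon"])
            rd = float(df.loc[bid, "release_day"])
            bearings.append(fall_bearing(release, det, release_day=rd, fall_window=fall_window))
            timings.append(fall_timing(rd, release, det, fall_window=fall_window))
        out["fall_bearing"] = bearings
        out["fall_timing"] = timings
    return out[list(CANDIDATE_FEATURES)]


@dataclass
class PreparedFeatures:
    """Model-ready matrices plus the preprocessing provenance."""

    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    feature_names: list
    dropped_correlated: list
    dropped_missing: list
    standardizer: Standardizer
    imputed_mask: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray


def prepare_features(
    candidates: pd.DataFrame,
    labels,
    mode: str = "paper-literal",
    test_frac: float = 0.2,
    seed: int = 0,
    corr_threshold: float = 0.7,
    max_missing: float = 0.25,
    k_impute: int = 5,
) -> PreparedFeatures:
    """Full preprocessing chain: prune -> filter -> standardize -> impute ->
    split (paper-literal) or prune -> filter -> split -> fit-on-train
    standardize/impute (strict)."""
    labels = np.asarray(labels, dtype=int)
    if mode not in ("paper-literal", "strict"):
        raise ValueError(f"unknown mode: {mode!r}")
    kept = correlation_prune(candidates, threshold=corr_threshold)
    dropped_corr = [c for c in candidates.columns if c not in kept]
    table = candidates[kept]
    kept2 = missingness_filter(table, max_frac=max_missing)
    dropped_miss = [c for c in table.columns if c not in kept2]
    table = table[kept2]

    if mode == "paper-literal":
        std = Standardizer()
        z = std.fit_transform(table)
        full, mask = knn_impute(z, k=k_impute)
        train_idx, test_idx = stratified_split(labels, test_frac=test_frac, seed=seed)
        X_train = full.iloc[train_idx]
        X_test = full.iloc[test_idx]
    else:
        train_idx, test_idx = stratified_split(labels, test_frac=test_frac, seed=seed)
        std = Standardizer().fit(table.iloc[train_idx])
        z_train = std.transform(table.iloc[train_idx])
        z_test = std.transform(table.iloc[test_idx])
        X_train, mask_train = knn_impute(z_train, k=k_impute)
        X_test, mask_test = knn_impute(z_test, k=k_impute, fit_table=z_train)
        mask = pd.concat([mask_train, mask_test]).loc[table.index]
    # sex imputed like any feature, then snapped back to a class
    if "sex" in table.columns:
        for part in (X_train, X_test):
            observed = sorted(table["sex"].dropna().unique())
            if observed:
                z_levels = [(v - std.means["sex"]) / std.sds["sex"] for v in observed]
                arr = part["sex"].to_numpy()
                snapped = [min(z_levels, key=lambda z0: abs(z0 - v)) for v in arr]
                part.loc[:, "sex"] = snapped
    return PreparedFeatures(
        X_train=X_train,
        X_test=X_test,
        y_train=labels[train_idx],
        y_test=labels[test_idx],
        feature_names=list(table.columns),
        dropped_correlated=dropped_corr,
        dropped_missing=dropped_miss,
        standardizer=std,
        imputed_mask=mask,
        train_idx=train_idx,
        test_idx=test_idx,
    )
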