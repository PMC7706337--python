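"""Integrative statistics over sensor, image and physiology outputs.

The feature table pools plant-by-timepoint rows of the six study variables —
compactness (C), green index (GI), stomatal conductance (SC), sensor response
(R), NIR intensity (NI) and digital biovolume (DB) — and supports Pearson
correlations, a full pairwise correlation matrix, a correlation-matrix PCA
with biplot export, and per-timepoint two-group tests (Student's t or one-way
ANOVA) with significance stars.

The sensor response enters the table as the magnitude of the per-plant daily
mean R on each imaging day (nearest-day join): the raw response is negative,
and its magnitude is the quantity that tracks sap ion content and
transpiration, so correlations against conductance and biovolume carry the
physiologically meaningful sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CONTROL, STRESSED

__all__ = [
    "FEATURE_COLUMNS",
    "STAR_MAPS",
    "PcaResult",
    "pearson",
    "correlation_matrix",
    "run_pca",
    "timepoint_tests",
    "build_feature_table",
    "assign_stars",
    "pc1_group_separation",
]

FEATURE_COLUMNS = ("C", "GI", "SC", "R", "NI", "DB")

# conventional thresholds; the "paper" preset mirrors a published figure
# caption whose ordering of * and ** is internally inverted
STAR_MAPS: dict[str, list[tuple[float, str]]] = {
    "conventional": [
        (0.0001, "****"),
        (0.001, "***"),
        (0.01, "**"),
        (0.05, "*"),
    ],
    "paper": [
        (0.0001, "****"),
        (0.001, "***"),
        (0.05, "**"),
        (0.01, "*"),
    ],
}


def assign_stars(p: float, star_map: str | list[tuple[float, str]] = "conventional") -> str:
    if isinstance(star_map, str):
        star_map = STAR_MAPS[star_map]
    for threshold, stars in sorted(star_map):
        if p <= threshold:
            return stars
    return ""


# ---------------------------------------------------------------------------
# correlation


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson matrix over the six study variables.

    Uses pairwise-complete rows per cell and reports r, p and n for each
    variable pair in long form; r is 1 on the diagonal. Raises when any
    variable is constant on its complete rows.
    """
    rows = []
    for i, a in enumerate(FEATURE_COLUMNS):
        for b in FEATURE_COLUMNS[i:]:
            sub = table[[a, b]].dropna()
            n = len(sub)
            if a == b:
                if np.ptp(sub[a].to_numpy()) == 0:
                    raise ValueError(f"variable {a} is constant")
                r, p = 1.0, 0.0
            else:
                if n < 3:
                    raise ValueError(f"fewer than 3 complete rows for ({a}, {b})")
                r, p = pearson(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "n": n})
            if a != b:
                rows.append({"var_a": b, "var_b": a, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame            # rows x components, with group labels
    loadings: pd.DataFrame          # variables x components, orthonormal
    variance_explained: np.ndarray  # percent per component, sums to 100
    n_rows: int
    n_excluded: int

    def biplot_data(self, scale: float | None = None) -> dict:
        """Scores plus loadings rescaled for co-plotting on the score axes."""
        sc = self.scores[["PC1", "PC2"]].to_numpy()
        ld = self.loadings[["PC1", "PC2"]].to_numpy()
        if scale is None:
            scale = float(np.abs(sc).max() / max(np.abs(ld).max(), 1e-12)) * 0.7
        return {
            "scores": self.scores.to_dict(orient="records"),
            "loadings": [
                {
                    "variable": v,
                    "PC1": float(ld[i, 0] * scale),
                    "PC2": float(ld[i, 1] * scale),
                }
                for i, v in enumerate(self.loadings.index)
            ],
            "variance_explained_pct": [float(v) for v in self.variance_explained],
            "loading_scale": scale,
        }


def run_pca(
    table: pd.DataFrame,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
    standardize: bool = True,
) -> PcaResult:
    """PCA of the standardized feature table (correlation-matrix PCA).

    Rows with any missing value are excluded (and counted); variables are
    centered and scaled to unit variance, so components diagonalize the
    correlation matrix (the variables have incommensurate units). Pass
    ``standardize=False`` to decompose the covariance of pre-scaled data.
    Returns scores, orthonormal loadings and the percent variance per
    component (summing to 100 over all computed components).
    """
    cols = [c for c in columns if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 variables for PCA")
    complete = table.dropna(subset=cols)
    n_excluded = len(table) - len(complete)
    X = complete[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete rows for PCA")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant column(s) in PCA input: {bad}")
    Z = X - X.mean(axis=0)
    if standardize:
        Z = Z / sd

    # SVD of the standardized matrix == eigendecomposition of the correlation
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    var_pct = 100.0 * eig / eig.sum()
    scores = Z @ vt.T

    comp_names = [f"PC{i + 1}" for i in range(len(eig))]
    score_df = pd.DataFrame(scores, columns=comp_names, index=complete.index)
    for meta in ("plant_id", "day", "group"):
        if meta in complete.columns:
            score_df[meta] = complete[meta].to_numpy()
    loading_df = pd.DataFrame(vt.T, index=cols, columns=comp_names)
    return PcaResult(
        scores=score_df,
        loadings=loading_df,
        variance_explained=var_pct,
        n_rows=X.shape[0],
        n_excluded=n_excluded,
    )


def pc1_group_separation(pca: PcaResult) -> float:
    """Group-mean PC1 difference in units of the pooled within-group SD."""
    sc = pca.scores
    a = sc.loc[sc["group"] == CONTROL, "PC1"].to_numpy()
    b = sc.loc[sc["group"] == STRESSED, "PC1"].to_numpy()
    n1, n2 = len(a), len(b)
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    return float(abs(a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# per-timepoint tests


def timepoint_tests(
    long: pd.DataFrame,
    method: str = "anova",
    star_map: str | list[tuple[float, str]] = "conventional",
) -> pd.DataFrame:
    """Two-group test per day x variable with significance stars.

    ``long`` holds columns group, day, variable, value. ``method`` is
    ``"t_test"`` (two-sample, equal variance) or ``"anova"`` (one-way); with
    two groups the ANOVA F statistic equals the squared t statistic. P-values
    are reported unadjusted.
    """
    if method not in ("t_test", "anova"):
        raise ValueError("method must be 't_test' or 'anova'")
    rows = []
    for (day, variable), sub in long.groupby(["day", "variable"], sort=True):
        groups = {g: s["value"].to_numpy(dtype=float) for g, s in sub.groupby("group")}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"need >= 2 values per group at day {day}, {variable}")
        samples = [groups[g] for g in sorted(groups)]
        if method == "t_test":
            res = sps.ttest_ind(*samples, equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = sps.f_oneway(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # identical constant groups
            stat, p = 0.0, 1.0
        rows.append(
            {
                "day": day,
                "variable": variable,
                "method": method,
                "statistic": stat,
                "p_value": p,
                "stars": assign_stars(p, star_map),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature table assembly


def _nearest_join(days: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index into ``targets`` of the nearest day for each requested day."""
    targets = np.asarray(targets, dtype=float)
    out = np.empty(len(days), dtype=int)
    for i, d in enumerate(days):
        out[i] = int(np.argmin(np.abs(targets - d)))
    return out


def build_feature_table(
    indices: pd.DataFrame,
    daily_r: pd.DataFrame,
    physio: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the plant x imaging-day feature table of the six variables.

    ``indices`` is the imaging output (plant_id, day, biovolume, height_px,
    compactness, green_index, nir_index); ``daily_r`` the per-plant daily mean
    response with group labels; ``physio`` the long physiology table (for SC).
    R and SC are joined to each imaging day by nearest available day; R enters
    as the magnitude of the daily mean response. Rows with missing values are
    kept (flagged to PCA by their NaNs).
    """
    out = indices.rename(
        columns={
            "compactness": "C",
            "green_index": "GI",
            "nir_index": "NI",
            "biovolume": "DB",
        }
    ).copy()

    group_of = (
        daily_r.groupby("plant_id")["group"].first()
        if "group" in daily_r.columns
        else None
    )
    r_col = np.full(len(out), np.nan)
    sc_col = np.full(len(out), np.nan)
    grp = []
    sc = physio[physio["measure"] == "SC"]
    for i, (plant, day) in enumerate(zip(out["plant_id"], out["day"])):
        rp = daily_r[daily_r["plant_id"] == plant]
        if len(rp):
            j = _nearest_join(np.array([day]), rp["day"].to_numpy())[0]
            r_col[i] = abs(float(rp["r_mean"].to_numpy()[j]))
        scp = sc[sc["plant_id"] == plant]
        if len(scp):
            by_day = scp.groupby("day")["value"].mean()
            j = _nearest_join(np.array([day]), by_day.index.to_numpy())[0]
            sc_col[i] = float(by_day.to_numpy()[j])
        grp.append(group_of.get(plant) if group_of is not None else None)
    out["R"] = r_col
    out["SC"] = sc_col
    if "group" not in out.columns:
        out["group"] = grp
    cols = ["plant_id", "day", "group", *FEATURE_COLUMNS]
    return out[[c for c in cols if c in out.columns]]
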