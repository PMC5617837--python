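"""Hierarchical weighted scan -> peptide -> protein quantification (Zq).

Model
-----
Each scan-level log2 ratio of a protein q under one condition decomposes as

    x_s = mu_q + e_P + e_S,    e_P ~ N(0, sigma_P^2),  e_S ~ N(0, sigma_S^2(I)),

with a scan error whose variance may depend on spectral intensity, a
peptide-level deviation and a protein-level true change mu_q. Estimates are
inverse-variance weighted at every level:

    x_p = sum w_s x_s / sum w_s,          w_s = 1 / sigma_S^2(I_s)
    x_q = sum W_p x_p / sum W_p,          W_p = 1 / (v_p + sigma_P^2)

The variance components are calibrated by moment matching: sigma_P^2 is the
value that gives the standardized peptide residuals unit sample variance
(over peptides of multi-peptide proteins), and sigma_Q^2 analogously for the
standardized protein deviations from the weighted grand mean. The final
protein statistic

    Zq = (x_q - grand_mean) * sqrt(W_q),  W_q = 1 / (v_q + sigma_Q^2)

expresses each protein's log2 fold change in units of standard deviation
around the average and is ~N(0, 1) for unchanged proteins. Conditions
(region x timepoint) are standardized independently. No minimum number of
peptides per protein is imposed: single-peptide, single-scan proteins are
retained with correspondingly wide variances.

``WsppModel(scan_table).fit()`` runs the full hierarchy and returns a
:class:`WsppResults` with per-protein scores and the fitted components; the
stage functions (:func:`fit_scan_variance`, :func:`aggregate_peptides`,
:func:`aggregate_proteins`, :func:`estimate_variance_components`,
:func:`standardize`) are also usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, isotonic_regression

__all__ = [
    "SCAN_COLUMNS",
    "ScanVarianceModel",
    "VarianceComponents",
    "WsppModel",
    "WsppResults",
    "validate_scan_table",
    "fit_scan_variance",
    "aggregate_peptides",
    "aggregate_proteins",
    "estimate_variance_components",
    "standardize",
]

SCAN_COLUMNS = (
    "scan_id",
    "peptide",
    "protein",
    "region",
    "timepoint",
    "log2_ratio",
    "intensity",
)

_VAR_FLOOR = 1e-12  # guards weights on (near-)noise-free synthetic data


@dataclass(frozen=True)
class ScanVarianceModel:
    """Piecewise-constant scan variance as a function of spectral intensity.

    ``edges`` are the interior intensity boundaries (len n_bins - 1) and
    ``variances`` the per-bin values, non-increasing in intensity.
    """

    edges: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "variances", v)
        if v.size != e.size + 1:
            raise ValueError("need one variance per bin (len(edges) + 1)")
        if np.any(v < 0):
            raise ValueError("variances must be >= 0")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("scan variance must be non-increasing in intensity")

    def __call__(self, intensity) -> np.ndarray:
        idx = np.searchsorted(self.edges, np.asarray(intensity, dtype=float), side="right")
        return self.variances[idx]


@dataclass(frozen=True)
class VarianceComponents:
    """The three error levels of the hierarchy for one condition."""

    scan_model: ScanVarianceModel
    sigma_P2: float
    sigma_Q2: float

    def __post_init__(self):
        if self.sigma_P2 < 0 or self.sigma_Q2 < 0:
            raise ValueError("variance components must be >= 0")


def validate_scan_table(scans: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a scan-level quantification table."""
    missing = set(SCAN_COLUMNS) - set(scans.columns)
    if missing:
        raise ValueError(f"scan table missing columns: {sorted(missing)}")
    x = scans["log2_ratio"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        rows = np.flatnonzero(~np.isfinite(x))[:5].tolist()
        raise ValueError(f"non-finite log2_ratio at rows {rows}")
    inten = scans["intensity"].to_numpy(dtype=float)
    if np.any(~np.isfinite(inten)) or np.any(inten <= 0):
        rows = np.flatnonzero(~np.isfinite(inten) | (inten <= 0))[:5].tolist()
        raise ValueError(f"intensities must be positive and finite (rows {rows})")
    n_prot = scans.groupby("peptide", sort=False)["protein"].nunique()
    shared = n_prot[n_prot > 1]
    if len(shared):
        raise ValueError(
            f"peptides mapped to multiple proteins: {shared.index[:5].tolist()}"
        )
    return scans


# ---------------------------------------------------------------------------
# scan level


def fit_scan_variance(
    scans: pd.DataFrame, n_bins: int = 5, min_scans_for_binning: int = 500
) -> ScanVarianceModel:
    """Scan-level variance from within-peptide replicate scatter.

    Residuals about the per-(peptide, condition) mean are pooled into
    ``n_bins`` equal-count intensity bins and the bin variances are made
    non-increasing in intensity by pooled-adjacent-violators. A constant
    (single-bin) model is used when ``n_bins == 1`` or fewer than
    ``min_scans_for_binning`` scans contribute residual degrees of freedom.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    g = scans.groupby(["peptide", "region", "timepoint"], sort=False).ngroup().to_numpy()
    x = scans["log2_ratio"].to_numpy(dtype=float)
    inten = scans["intensity"].to_numpy(dtype=float)
    k = g.max() + 1
    n = np.bincount(g, minlength=k)
    mean = np.bincount(g, weights=x, minlength=k) / n
    r = x - mean[g]
    dfw = (n[g] - 1) / n[g]  # per-scan share of the within-group df
    contrib = n[g] >= 2
    if not contrib.any():
        raise ValueError(
            "no peptide has two or more scans in any condition: "
            "scan variance is unidentifiable"
        )
    r2, dfw, inten_c = r[contrib] ** 2, dfw[contrib], inten[contrib]
    if n_bins == 1 or contrib.sum() < min_scans_for_binning:
        var = float(r2.sum() / dfw.sum())
        return ScanVarianceModel(edges=np.empty(0), variances=np.array([var]))
    edges = np.quantile(inten_c, np.linspace(0, 1, n_bins + 1))[1:-1]
    idx = np.searchsorted(edges, inten_c, side="right")
    ss = np.bincount(idx, weights=r2, minlength=n_bins)
    df = np.bincount(idx, weights=dfw, minlength=n_bins)
    overall = r2.sum() / dfw.sum()
    var = np.where(df > 0, ss / np.where(df > 0, df, 1.0), overall)
    weights = np.where(df > 0, df, 1e-9)
    mono = isotonic_regression(var, weights=weights, increasing=False)
    return ScanVarianceModel(edges=edges, variances=np.maximum(mono.x, 0.0))


# ---------------------------------------------------------------------------
# internal array helpers (one condition)


def _weighted_means(codes: np.ndarray, k: int, x: np.ndarray, w: np.ndarray):
    sw = np.bincount(codes, weights=w, minlength=k)
    swx = np.bincount(codes, weights=w * x, minlength=k)
    return swx / sw, 1.0 / sw


def _sigma_p2_moment(s: float, x_p, v_p, prot_codes, n_prot, n_pep_of) -> float:
    W = 1.0 / (v_p + s)
    x_q, inv_sw = _weighted_means(prot_codes, n_prot, x_p, W)
    multi = n_pep_of[prot_codes] >= 2  # leverage denominator vanishes otherwise
    denom = (v_p + s)[multi] - inv_sw[prot_codes[multi]]
    z2 = (x_p[multi] - x_q[prot_codes[multi]]) ** 2 / denom
    return float(z2.mean())


def _sigma_q2_moment(s: float, x_q, v_q) -> float:
    W = 1.0 / (v_q + s)
    sw = W.sum()
    gm = (W * x_q).sum() / sw
    denom = (v_q + s) - 1.0 / sw
    return float(((x_q - gm) ** 2 / denom).mean())


def _solve_moment(f) -> float:
    """Smallest s >= 0 with f(s) = 1 for a decreasing moment function f."""
    if f(0.0) <= 1.0:
        return 0.0
    hi = 1.0
    while f(hi) > 1.0:
        hi *= 4.0
        if hi > 1e8:  # pragma: no cover - pathological inputs
            return hi
    return float(brentq(lambda s: f(s) - 1.0, 0.0, hi, xtol=1e-10, rtol=1e-8))


# ---------------------------------------------------------------------------
# stage functions (pandas in / pandas out)


def aggregate_peptides(scans: pd.DataFrame, scan_model: ScanVarianceModel) -> pd.DataFrame:
    """Inverse-variance weighted peptide estimates x_p with variance v_p."""
    w = 1.0 / np.maximum(scan_model(scans["intensity"].to_numpy(dtype=float)), _VAR_FLOOR)
    x = scans["log2_ratio"].to_numpy(dtype=float)
    keys = scans[["peptide", "protein", "region", "timepoint"]]
    g = keys.groupby(["peptide", "region", "timepoint"], sort=False).ngroup().to_numpy()
    k = g.max() + 1
    x_p, v_p = _weighted_means(g, k, x, w)
    first = np.full(k, -1, dtype=np.int64)
    first[g[::-1]] = np.arange(len(g) - 1, -1, -1)
    out = keys.iloc[first].reset_index(drop=True)
    out["x_p"] = x_p
    out["v_p"] = v_p
    out["n_scans"] = np.bincount(g, minlength=k)
    return out


def aggregate_proteins(peptides: pd.DataFrame, sigma_P2: float) -> pd.DataFrame:
    """Protein estimates x_q, v_q from peptide estimates.

    Weights are W_p = 1/(v_p + sigma_P2); single-peptide proteins are
    retained (their v_q is simply v_p + sigma_P2).
    """
    if sigma_P2 < 0:
        raise ValueError("sigma_P2 must be >= 0")
    if len(peptides) == 0:
        raise ValueError("no peptides to aggregate")
    keys = peptides[["protein", "region", "timepoint"]]
    g = keys.groupby(["protein", "region", "timepoint"], sort=False).ngroup().to_numpy()
    k = g.max() + 1
    W = 1.0 / (peptides["v_p"].to_numpy(dtype=float) + sigma_P2)
    x_q, v_q = _weighted_means(g, k, peptides["x_p"].to_numpy(dtype=float), W)
    first = np.full(k, -1, dtype=np.int64)
    first[g[::-1]] = np.arange(len(g) - 1, -1, -1)
    out = keys.iloc[first].reset_index(drop=True)
    out["x_q"] = x_q
    out["v_q"] = v_q
    out["n_peptides"] = np.bincount(g, minlength=k)
    out["n_scans"] = np.bincount(g, weights=peptides["n_scans"].to_numpy(float), minlength=k).astype(int)
    return out


def estimate_variance_components(scans: pd.DataFrame, n_bins: int = 5) -> VarianceComponents:
    """Moment-matched peptide- and protein-level variance components.

    sigma_P^2 makes the standardized peptide residuals
    z_p = (x_p - x_q) / sqrt(1/W_p - 1/sum W_p) have unit sample variance
    over peptides of multi-peptide proteins; sigma_Q^2 does the same for the
    standardized protein deviations from the weighted grand mean, per
    condition (pooled across the table's conditions here). Both are clipped
    at zero.
    """
    validate_scan_table(scans)
    scan_model = fit_scan_variance(scans, n_bins=n_bins)
    peptides = aggregate_peptides(scans, scan_model)

    g = peptides.groupby(["protein", "region", "timepoint"], sort=False).ngroup().to_numpy()
    k = g.max() + 1
    n_pep_of = np.bincount(g, minlength=k)
    x_p = peptides["x_p"].to_numpy(dtype=float)
    v_p = peptides["v_p"].to_numpy(dtype=float)
    if (n_pep_of >= 2).sum() == 0:
        warnings.warn("no multi-peptide proteins: sigma_P^2 set to 0")
        sigma_P2 = 0.0
    else:
        sigma_P2 = _solve_moment(lambda s: _sigma_p2_moment(s, x_p, v_p, g, k, n_pep_of))

    proteins = aggregate_proteins(peptides, sigma_P2)
    x_q_all = proteins["x_q"].to_numpy(dtype=float)
    v_q_all = proteins["v_q"].to_numpy(dtype=float)
    cond = proteins.groupby(["region", "timepoint"], sort=False).ngroup().to_numpy()

    def pooled_q_moment(s: float) -> float:
        z2 = [
            _sigma_q2_moment(s, x_q_all[cond == c], v_q_all[cond == c]) * (cond == c).sum()
            for c in range(cond.max() + 1)
        ]
        return float(sum(z2) / len(cond))

    sigma_Q2 = _solve_moment(pooled_q_moment)
    return VarianceComponents(scan_model=scan_model, sigma_P2=sigma_P2, sigma_Q2=sigma_Q2)


def standardize(proteins: pd.DataFrame, sigma_Q2: float) -> pd.DataFrame:
    """Standardized protein changes Zq = (x_q - grand_mean) * sqrt(W_q).

    The weighted grand mean and the standardization are computed per
    condition (region x timepoint).
    """
    if len(proteins) == 0:
        raise ValueError("no protein estimates to standardize")
    if sigma_Q2 < 0:
        raise ValueError("sigma_Q2 must be >= 0")
    v_q = proteins["v_q"].to_numpy(dtype=float)
    if np.any(v_q + sigma_Q2 <= 0):
        raise ValueError("degenerate total variance v_q + sigma_Q2 <= 0")
    out = proteins.copy()
    zq = np.empty(len(out))
    cond = out.groupby(["region", "timepoint"], sort=False).ngroup().to_numpy()
    x_q = out["x_q"].to_numpy(dtype=float)
    for c in range(cond.max() + 1):
        m = cond == c
        W = 1.0 / (v_q[m] + sigma_Q2)
        gm = (W * x_q[m]).sum() / W.sum()
        zq[m] = (x_q[m] - gm) * np.sqrt(W)
    out["Zq"] = zq
    return out


# ---------------------------------------------------------------------------
# model / results


class WsppModel:
    """Hierarchical weighted quantification model over a scan-level table.

    Parameters
    ----------
    scans
        Long table with columns ``scan_id, peptide, protein, region,
        timepoint, log2_ratio, intensity``; one row per scan per condition.
    n_bins
        Equal-count intensity bins for the scan-variance curve.
    """

    def __init__(self, scans: pd.DataFrame, n_bins: int = 5):
        self.scans = validate_scan_table(scans)
        self.n_bins = int(n_bins)

    @classmethod
    def from_tsv(cls, path, n_bins: int = 5) -> "WsppModel":
        from .io import read_scan_table

        return cls(read_scan_table(path), n_bins=n_bins)

    def fit(self) -> "WsppResults":
        """Fit the scan-variance curve, the per-condition variance components,
        and standardize every protein to Zq."""
        scan_model = fit_scan_variance(self.scans, n_bins=self.n_bins)
        peptides = aggregate_peptides(self.scans, scan_model)
        cond_codes = peptides.groupby(["region", "timepoint"], sort=False).ngroup().to_numpy()
        components: dict[tuple[str, str], VarianceComponents] = {}
        pieces = []
        for c in range(cond_codes.max() + 1):
            pep_c = peptides[cond_codes == c]
            region = pep_c["region"].iloc[0]
            timepoint = pep_c["timepoint"].iloc[0]
            g = pd.factorize(pep_c["protein"], sort=False)[0]
            k = g.max() + 1
            n_pep_of = np.bincount(g, minlength=k)
            x_p = pep_c["x_p"].to_numpy(dtype=float)
            v_p = pep_c["v_p"].to_numpy(dtype=float)
            if (n_pep_of >= 2).sum() == 0:
                warnings.warn(
                    f"condition ({region}, {timepoint}): no multi-peptide proteins; "
                    "sigma_P^2 set to 0"
                )
                sp2 = 0.0
            else:
                sp2 = _solve_moment(
                    lambda s: _sigma_p2_moment(s, x_p, v_p, g, k, n_pep_of)
                )
            prot_c = aggregate_proteins(pep_c, sp2)
            sq2 = _solve_moment(
                lambda s: _sigma_q2_moment(
                    s, prot_c["x_q"].to_numpy(float), prot_c["v_q"].to_numpy(float)
                )
            )
            components[(region, timepoint)] = VarianceComponents(scan_model, sp2, sq2)
            pieces.append(standardize(prot_c, sq2))
        scores = (
            pd.concat(pieces, ignore_index=True)
            .sort_values(["protein", "region", "timepoint"], kind="mergesort")
            .reset_index(drop=True)
        )
        return WsppResults(model=self, scan_model=scan_model, components=components, protein_scores=scores)


@dataclass
class WsppResults:
    """Fitted quantification: per-protein scores and variance components.

    ``protein_scores`` has one row per protein per condition with columns
    ``protein, region, timepoint, x_q, v_q, Zq, n_peptides, n_scans``.
    """

    model: WsppModel
    scan_model: ScanVarianceModel
    components: dict = field(repr=False)
    protein_scores: pd.DataFrame = field(repr=False)

    def zq_matrix(self) -> pd.DataFrame:
        """Proteins x conditions matrix of Zq (columns are (region, timepoint))."""
        return self.protein_scores.pivot_table(
            index="protein", columns=["region", "timepoint"], values="Zq"
        )

    def summary(self) -> str:
        scores = self.protein_scores
        lines = [
            "Weighted scan-peptide-protein quantification",
            "=" * 60,
            f"scans: {len(self.model.scans):>8d}    proteins: {scores['protein'].nunique()}",
            f"conditions: {len(self.components)}    intensity bins: {self.scan_model.variances.size}",
            f"scan variance (log2^2): {np.array2string(self.scan_model.variances, precision=4)}",
            "-" * 60,
            f"{'region':<12}{'timepoint':<12}{'sigma_P':>10}{'sigma_Q':>10}{'Zq SD':>10}",
        ]
        for (region, timepoint), comp in sorted(self.components.items()):
            m = (scores["region"] == region) & (scores["timepoint"] == timepoint)
            sd = scores.loc[m, "Zq"].std(ddof=1)
            lines.append(
                f"{region:<12}{timepoint:<12}"
                f"{np.sqrt(comp.sigma_P2):>10.4f}{np.sqrt(comp.sigma_Q2):>10.4f}{sd:>10.4f}"
            )
        return "\n".join(lines)
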