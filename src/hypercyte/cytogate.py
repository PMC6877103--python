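"""Ploidy, cell-cycle, viability and marker gating of per-nucleus features.

Gating reproduces image-cytometry practice for a near-triploid line: the
dominant mode of the control integrated-Hoechst histogram anchors the G1
(3N) peak, twice that anchors G2 (6N), and everything beyond the right edge
of the G2 gate is the hyperploid (supraG2, >6N) class.  S phase is called
from EdU positivity; viability from the propidium-iodide × caspase-indicator
plane; marker positivity from either a bimodal-midpoint threshold or a
control-percentile rule; cleaved-PARP from a two-dimensional (intensity ×
nuclear-to-cytoplasmic ratio) boundary calibrated to flag ~2% of the
untreated bulk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from . import CYCLE_CLASSES


class GatingError(ValueError):
    pass


class BimodalityError(GatingError):
    """Raised when a distribution shows no clear two-component structure."""


@dataclass(frozen=True)
class PloidyAnchors:
    """DNA-content anchors: 3N = G1 peak of the near-triploid line, 6N = 2×3N."""

    anchor_3n: float
    cv_est: float

    @property
    def anchor_6n(self) -> float:
        return 2.0 * self.anchor_3n

    def __post_init__(self):
        if self.anchor_3n <= 0:
            raise GatingError("anchor_3n must be > 0")
        if not 0.0 < self.cv_est < 1.0:
            raise GatingError("cv_est must be in (0, 1)")


@dataclass
class GateSet:
    """All thresholds used to label per-nucleus records."""

    anchors: PloidyAnchors
    debris_threshold: float
    pi_threshold: float
    caspase_threshold: float
    edu_threshold: float
    g1_window: tuple[float, float]
    g2_window: tuple[float, float]
    marker_thresholds: dict = field(default_factory=dict)
    cparp_rule: dict | None = None

    @property
    def suprag2_threshold(self) -> float:
        """Hyperploid boundary = right end of the G2 gated region."""
        return self.g2_window[1]

    def validate(self) -> None:
        seq = (
            self.debris_threshold,
            self.g1_window[0],
            self.g1_window[1],
            self.g2_window[0],
            self.g2_window[1],
        )
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise GatingError(
                "gate ordering violated: need debris < g1.low < g1.high "
                f"< g2.low < g2.high, got {seq}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchors"] = {"anchor_3n": self.anchors.anchor_3n,
                        "anchor_6n": self.anchors.anchor_6n,
                        "cv_est": self.anchors.cv_est}
        d["g1_window"] = list(self.g1_window)
        d["g2_window"] = list(self.g2_window)
        d["suprag2_threshold"] = self.suprag2_threshold
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        anchors = PloidyAnchors(
            anchor_3n=float(d["anchors"]["anchor_3n"]),
            cv_est=float(d["anchors"]["cv_est"]),
        )
        return cls(
            anchors=anchors,
            debris_threshold=float(d["debris_threshold"]),
            pi_threshold=float(d["pi_threshold"]),
            caspase_threshold=float(d["caspase_threshold"]),
            edu_threshold=float(d["edu_threshold"]),
            g1_window=tuple(map(float, d["g1_window"])),
            g2_window=tuple(map(float, d["g2_window"])),
            marker_thresholds=dict(d.get("marker_thresholds") or {}),
            cparp_rule=d.get("cparp_rule"),
        )


# ---------------------------------------------------------------------------
# threshold primitives

def fit_ploidy_anchors(values, min_n: int = 100) -> PloidyAnchors:
    """Anchor 3N at the dominant density mode of control DNA contents.

    The G1 coefficient of variation is estimated from the full width at half
    maximum of the mode.  Scale-equivariant: multiplying the input by c > 0
    scales both anchors by c and leaves cv_est unchanged.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if len(v) < min_n:
        raise GatingError(f"need >= {min_n} control values, got {len(v)}")
    if np.ptp(v) == 0:
        raise GatingError("no detectable mode: constant input")
    # narrow fixed-factor bandwidth so the G1 mode is not smeared into the
    # S/G2 arc; the factor multiplies the sample std, keeping the estimator
    # scale-equivariant
    bw_factor = 0.05
    kde = gaussian_kde(v, bw_method=bw_factor)
    grid = np.linspace(v.min(), v.max(), 2048)
    dens = kde(grid)
    i_mode = int(np.argmax(dens))
    mode = float(grid[i_mode])
    if mode <= 0:
        raise GatingError("non-positive mode location")

    half = dens[i_mode] / 2.0
    left = i_mode
    while left > 0 and dens[left] > half:
        left -= 1
    right = i_mode
    while right < len(grid) - 1 and dens[right] > half:
        right += 1
    fwhm = grid[right] - grid[left]
    sigma_obs = fwhm / 2.3548200450309493  # FWHM of a Gaussian
    # deconvolve the kernel width from the observed peak width
    bw = bw_factor * float(np.std(v))
    sigma = np.sqrt(max(sigma_obs**2 - bw**2, (0.005 * mode) ** 2))
    cv = float(np.clip(sigma / mode, 0.005, 0.5))
    return PloidyAnchors(anchor_3n=mode, cv_est=cv)


def threshold_bimodal_midpoint(values, min_n: int = 50) -> float:
    """Midpoint threshold between the two modes of a bimodal intensity
    histogram (two-component Gaussian mixture on log intensities; component
    means are mapped back to the intensity scale before taking the midpoint).

    Raises :class:`BimodalityError` when the components are not separated by
    at least two pooled standard deviations.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < min_n:
        raise GatingError(f"need >= {min_n} values, got {len(v)}")
    # winsorize the extreme tails so a handful of outliers cannot stretch a
    # mixture component and defeat the separation check
    v = np.clip(v, np.percentile(v, 0.1), np.percentile(v, 99.9))
    logv = np.log(v).reshape(-1, 1)
    if np.ptp(logv) == 0:
        raise BimodalityError("no bimodality: constant input")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", reg_covar=1e-8,
        n_init=3, random_state=0,
    ).fit(logv)
    m = np.sort(gm.means_.ravel())
    order = np.argsort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel())[order]
    pooled = np.sqrt(0.5 * (sds[0] ** 2 + sds[1] ** 2))
    if pooled <= 0 or (m[1] - m[0]) < 2.0 * pooled:
        raise BimodalityError(
            f"no bimodality: component separation {(m[1] - m[0]):.3g} "
            f"< 2 x pooled SD {pooled:.3g}"
        )
    lo, hi = np.exp(m)
    return float(0.5 * (lo + hi))


def threshold_control_percentile(control_values, q: float) -> float:
    """q-th percentile of untreated viable control values (linear
    interpolation); positivity downstream means strictly above it."""
    v = np.asarray(control_values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise GatingError("empty control sample")
    if not 0.0 < q < 100.0:
        raise GatingError("q must be in (0, 100)")
    return float(np.percentile(v, q, method="linear"))


def fit_cparp_rule(
    control_records: pd.DataFrame,
    target: float = 0.02,
    intensity_col: str = "mean_cparp",
    nc_col: str = "nc_ratio_cparp",
) -> dict:
    """Calibrate the 2D cleaved-PARP boundary on the untreated bulk.

    A common percentile level is applied on both axes (mean nuclear intensity
    and N:C ratio); the level is searched so that the fraction of control
    cells above BOTH cutoffs — i.e. separated from the main viable cluster —
    is as close as possible to ``target`` (~2%).
    """
    for col in (intensity_col, nc_col):
        if col not in control_records.columns:
            raise GatingError(f"control table lacks column {col!r}")
    x = control_records[intensity_col].to_numpy(float)
    y = control_records[nc_col].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 50:
        raise GatingError("need >= 50 control cells for the cleaved-PARP rule")
    if np.std(x) == 0 or np.std(y) == 0:
        raise GatingError("degenerate control: zero variance on an axis")

    levels = np.linspace(50.0, 99.95, 800)
    best = None
    for p in levels:
        cx = np.percentile(x, p)
        cy = np.percentile(y, p)
        frac = float(np.mean((x > cx) & (y > cy)))
        err = abs(frac - target)
        if best is None or err < best[0]:
            best = (err, p, cx, cy, frac)
    _, p, cx, cy, frac = best
    return {
        "intensity_cutoff": float(cx),
        "nc_ratio_cutoff": float(cy),
        "percentile_level": float(p),
        "control_positivity": frac,
    }


def gate_cleaved_parp(
    records: pd.DataFrame,
    control_records: pd.DataFrame,
    target: float = 0.02,
) -> pd.Series:
    """Cleaved-PARP positivity flags for ``records`` using a boundary
    calibrated on ``control_records`` (see :func:`fit_cparp_rule`)."""
    rule = fit_cparp_rule(control_records, target=target)
    return apply_cparp_rule(records, rule)


def apply_cparp_rule(records: pd.DataFrame, rule: dict) -> pd.Series:
    flags = (records["mean_cparp"] > rule["intensity_cutoff"]) & (
        records["nc_ratio_cparp"] > rule["nc_ratio_cutoff"]
    )
    return flags.rename("pos_cparp")


# ---------------------------------------------------------------------------
# record-level gates

def gate_debris(records: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Sub-G1 debris flag: integrated Hoechst below the debris threshold
    (default 0.25 × the 3N anchor)."""
    return (records["integrated_hoechst"] < gates.debris_threshold).rename("is_debris")


def classify_viability(records: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Viability class from the PI × caspase-indicator plane.

    PI−/casp− → VIABLE; caspase alone → EARLY_APOPTOTIC; both → LATE_APOPTOTIC;
    PI alone → NECROTIC.  Thresholds act on mean nuclear intensities.
    """
    missing = [c for c in ("mean_pi", "mean_caspase") if c not in records.columns]
    if missing:
        warnings.warn(f"missing channels {missing}; viability UNASSIGNED")
        return pd.Series("UNASSIGNED", index=records.index, name="viability")
    pi_pos = records["mean_pi"] > gates.pi_threshold
    casp_pos = records["mean_caspase"] > gates.caspase_threshold
    out = np.where(
        pi_pos & casp_pos, "LATE_APOPTOTIC",
        np.where(pi_pos, "NECROTIC",
                 np.where(casp_pos, "EARLY_APOPTOTIC", "VIABLE")),
    )
    return pd.Series(out, index=records.index, name="viability")


def classify_cell_cycle(records: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Cycle/ploidy class for (viable, non-debris) records.

    EdU-positive → S; otherwise by integrated Hoechst: within the G1 window →
    G1, within the G2 window → G2, beyond the supraG2 boundary (right end of
    the G2 gate) → HYPER; anything between windows (or sub-G1 but above
    debris) → UNASSIGNED.
    """
    if gates.anchors is None:
        raise GatingError("ploidy anchors required")
    gates.validate()
    dna = records["integrated_hoechst"].to_numpy(float)
    edu_pos = (
        records["mean_edu"].to_numpy(float) > gates.edu_threshold
        if "mean_edu" in records.columns
        else np.zeros(len(records), dtype=bool)
    )
    g1lo, g1hi = gates.g1_window
    g2lo, g2hi = gates.g2_window
    out = np.full(len(records), "UNASSIGNED", dtype=object)
    out[(dna >= g1lo) & (dna <= g1hi)] = "G1"
    out[(dna >= g2lo) & (dna <= g2hi)] = "G2"
    out[dna > gates.suprag2_threshold] = "HYPER"
    out[edu_pos] = "S"
    return pd.Series(out, index=records.index, name="cycle")


# ---------------------------------------------------------------------------
# gate fitting and composition

def _marker_threshold(values, q: float = 99.5) -> float:
    """Bimodal midpoint when the histogram is bimodal, else the control
    q-percentile fallback."""
    try:
        return threshold_bimodal_midpoint(values)
    except (BimodalityError, GatingError):
        return threshold_control_percentile(values, q)


def fit_gateset(
    control_records: pd.DataFrame,
    k: float = 2.5,
    debris_factor: float = 0.25,
    percentile_q: float = 99.5,
    markers: tuple[str, ...] = ("ph3", "ph2ax", "ki67"),
    cparp_target: float = 0.02,
) -> GateSet:
    """Fit a complete :class:`GateSet` from untreated control records.

    Order of fitting: ploidy anchors (dominant mode of integrated Hoechst) →
    debris threshold (``debris_factor`` × 3N anchor) → PI and caspase
    thresholds (bimodal midpoint, percentile fallback) → viable reference →
    EdU and marker thresholds on the viable reference → G1/G2 windows at
    anchor × (1 ± k·cv) → cleaved-PARP 2D rule.
    """
    anchors = fit_ploidy_anchors(control_records["integrated_hoechst"])
    debris_thr = debris_factor * anchors.anchor_3n
    non_debris = control_records[control_records["integrated_hoechst"] >= debris_thr]

    pi_thr = _marker_threshold(non_debris["mean_pi"], percentile_q)
    casp_thr = _marker_threshold(non_debris["mean_caspase"], percentile_q)
    viable_ref = non_debris[
        (non_debris["mean_pi"] <= pi_thr) & (non_debris["mean_caspase"] <= casp_thr)
    ]
    if len(viable_ref) < 100:
        raise GatingError("fewer than 100 viable control cells after gating")

    edu_thr = _marker_threshold(viable_ref["mean_edu"], percentile_q)

    marker_thresholds = {}
    for m in markers:
        col = f"mean_{m}"
        if col in viable_ref.columns:
            marker_thresholds[m] = _marker_threshold(viable_ref[col], percentile_q)

    cv = anchors.cv_est
    g1 = (anchors.anchor_3n * (1 - k * cv), anchors.anchor_3n * (1 + k * cv))
    g2 = (anchors.anchor_6n * (1 - k * cv), anchors.anchor_6n * (1 + k * cv))

    cparp_rule = None
    if {"mean_cparp", "nc_ratio_cparp"} <= set(viable_ref.columns):
        cparp_rule = fit_cparp_rule(viable_ref, target=cparp_target)

    gates = GateSet(
        anchors=anchors,
        debris_threshold=debris_thr,
        pi_threshold=pi_thr,
        caspase_threshold=casp_thr,
        edu_threshold=edu_thr,
        g1_window=g1,
        g2_window=g2,
        marker_thresholds=marker_thresholds,
        cparp_rule=cparp_rule,
    )
    gates.validate()
    return gates


def apply_gateset(records: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Label every record: debris → viability → cycle → marker positivity.

    Returns one row per record (index-aligned) with ``is_debris``,
    ``viability``, ``cycle`` and ``pos_<marker>`` columns.  Cycle classes are
    assigned only to viable, non-debris records; everything else is
    UNASSIGNED, so debris / cycle classes partition the table.
    """
    gates.validate()
    labels = pd.DataFrame(index=records.index)
    if "cell_id" in records.columns:
        labels["cell_id"] = records["cell_id"]
    labels["is_debris"] = gate_debris(records, gates)
    labels["viability"] = classify_viability(records, gates)
    labels.loc[labels["is_debris"], "viability"] = "UNASSIGNED"

    cycle = pd.Series("UNASSIGNED", index=records.index, name="cycle", dtype=object)
    eligible = (~labels["is_debris"]) & (labels["viability"] == "VIABLE")
    if eligible.any():
        cycle.loc[eligible] = classify_cell_cycle(records.loc[eligible], gates)
    labels["cycle"] = cycle

    for m, thr in gates.marker_thresholds.items():
        col = f"mean_{m}"
        if col in records.columns:
            labels[f"pos_{m}"] = records[col] > thr
    if "mean_edu" in records.columns:
        labels["pos_edu"] = records["mean_edu"] > gates.edu_threshold
    if gates.cparp_rule is not None and {
        "mean_cparp", "nc_ratio_cparp"
    } <= set(records.columns):
        labels["pos_cparp"] = apply_cparp_rule(records, gates.cparp_rule)
    return labels


def class_fractions(labels: pd.DataFrame, include_unassigned: bool = True) -> pd.Series:
    """Cycle-class fractions among viable, non-debris records."""
    viable = labels[(~labels["is_debris"]) & (labels["viability"] == "VIABLE")]
    classes = list(CYCLE_CLASSES) + (["UNASSIGNED"] if include_unassigned else [])
    counts = viable["cycle"].value_counts()
    total = counts.reindex(classes).fillna(0).sum()
    if total == 0:
        return pd.Series(0.0, index=classes)
    return counts.reindex(classes).fillna(0) / total
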