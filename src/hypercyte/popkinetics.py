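"""Per-well population endpoints: survival, subpopulation kinetics, nuclear
area summaries, checkpoint-strength ratio, mitotic metrics, dose-response
and regrowth quantification.

All small-sample suppression follows the min-5 rules used throughout the
source figures: wells with fewer than 5 viable cells are suppressed, class
median areas need >= 5 nuclei of that class, and mitotic breakdowns need
>= 5 mitotic nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import CYCLE_CLASSES

MIN_CELLS = 5  # "wells with fewer than 5 cells were not included"


class KineticsError(ValueError):
    pass


def _viable(records: pd.DataFrame, labels: pd.DataFrame) -> pd.Index:
    m = (~labels["is_debris"]) & (labels["viability"] == "VIABLE")
    return labels.index[m]


def summarize_well(
    records: pd.DataFrame, labels: pd.DataFrame, min_cells: int = MIN_CELLS
) -> dict:
    """Counts, cycle-class fractions and median nuclear areas for one well.

    ``suppressed`` is set when the well has fewer than ``min_cells`` viable
    cells; per-class median areas are reported only for classes with at
    least ``min_cells`` nuclei.
    """
    meta = {}
    for key in ("well", "day", "condition"):
        if key in records.columns and len(records):
            meta[key] = records[key].iloc[0]
    idx = _viable(records, labels)
    n_viable = int(len(idx))
    out = {**meta, "n_total": int(len(records)), "n_viable": n_viable,
           "suppressed": n_viable < min_cells}

    non_debris = labels[~labels["is_debris"]]
    n_nd = len(non_debris)
    for v in ("VIABLE", "NECROTIC", "EARLY_APOPTOTIC", "LATE_APOPTOTIC"):
        out[f"frac_{v.lower()}"] = (
            float((non_debris["viability"] == v).mean()) if n_nd else np.nan
        )

    cyc = labels.loc[idx, "cycle"]
    areas = records.loc[idx, "area"]
    for c in list(CYCLE_CLASSES) + ["UNASSIGNED"]:
        sel = cyc == c
        n_c = int(sel.sum())
        out[f"count_{c}"] = n_c
        out[f"frac_{c}"] = (n_c / n_viable) if (n_viable and not out["suppressed"]) else np.nan
        out[f"median_area_{c}"] = (
            float(areas[sel].median()) if n_c >= min_cells else np.nan
        )
    return out


def summarize_wells(
    records: pd.DataFrame, labels: pd.DataFrame, min_cells: int = MIN_CELLS
) -> pd.DataFrame:
    """Per-well summaries over a full labeled table (grouped by
    well × day × condition)."""
    rows = []
    keys = [k for k in ("well", "day", "condition") if k in records.columns]
    lab = labels.set_axis(records.index)
    for _, grp in records.groupby(keys, sort=True):
        rows.append(summarize_well(grp, lab.loc[grp.index], min_cells))
    return pd.DataFrame(rows)


def normalize_survival(
    summaries: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    *,
    reference_day: int = 1,
    reference_condition: float = 0.0,
) -> pd.DataFrame:
    """Survival per well = viable count / mean viable count of the reference
    wells (vehicle on day 1), setting mean control survival to 1."""
    if reference is None:
        reference = summaries[
            (summaries["day"] == reference_day)
            & (summaries["condition"] == reference_condition)
        ]
    if len(reference) == 0:
        raise KineticsError("no reference wells")
    ref_mean = float(reference["n_viable"].mean())
    if ref_mean <= 0:
        raise KineticsError("reference wells have zero viable cells")
    out = summaries.copy()
    out["survival"] = out["n_viable"] / ref_mean
    return out


def chk1_damage_ratio(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    bulk_control_records: pd.DataFrame,
    min_cells: int = MIN_CELLS,
) -> float:
    """Checkpoint-strength ratio of G2-arrested cells.

    ratio = (mean pCHK1 of G2 cells / mean pCHK1 of same-day bulk control)
          / (mean pH2A.X of G2 cells / mean pH2A.X of same-day bulk control).

    Returns NaN (suppressed) when fewer than ``min_cells`` G2 cells are
    available.  Evaluating the bulk control against itself gives exactly 1.
    """
    for col in ("mean_pchk1", "mean_ph2ax"):
        if col not in records.columns or col not in bulk_control_records.columns:
            raise KineticsError(f"missing channel column {col!r}")
    idx = _viable(records, labels)
    g2 = records.loc[idx][labels.loc[idx, "cycle"] == "G2"]
    if len(g2) < min_cells:
        return float("nan")
    bulk_chk1 = float(bulk_control_records["mean_pchk1"].mean())
    bulk_h2ax = float(bulk_control_records["mean_ph2ax"].mean())
    if bulk_chk1 <= 0 or bulk_h2ax <= 0:
        raise KineticsError("non-positive bulk control mean")
    chk1 = float(g2["mean_pchk1"].mean()) / bulk_chk1
    h2ax = float(g2["mean_ph2ax"].mean()) / bulk_h2ax
    return chk1 / h2ax


def mitotic_metrics(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    min_cells: int = MIN_CELLS,
) -> dict:
    """Mitotic (pH3-positive) metrics for one well/condition.

    * ``mitotic_fraction`` — pH3+ among viable cells (suppressed below
      ``min_cells`` viable cells);
    * ``hyper_fraction_of_mitotic`` — fraction of mitotic nuclei with
      hyperploid (>6N) DNA content;
    * ``ph2ax_pos_mitotic_3n6n`` / ``ph2ax_pos_mitotic_hyper`` — pH2A.X
      positivity (control-percentile rule) among mitotic nuclei split by
      non-hyperploid (3N–6N) vs hyperploid content.

    Breakdown metrics are suppressed (NaN) with fewer than ``min_cells``
    mitotic nuclei.
    """
    if "pos_ph3" not in labels.columns:
        raise KineticsError("labels lack pos_ph3; fit a pH3 threshold first")
    idx = _viable(records, labels)
    n_viable = len(idx)
    out = {"n_viable": int(n_viable)}
    if n_viable < min_cells:
        out.update(
            mitotic_fraction=np.nan, n_mitotic=0,
            hyper_fraction_of_mitotic=np.nan,
            ph2ax_pos_mitotic_3n6n=np.nan, ph2ax_pos_mitotic_hyper=np.nan,
        )
        return out

    mit = labels.loc[idx, "pos_ph3"]
    n_mit = int(mit.sum())
    out["mitotic_fraction"] = n_mit / n_viable
    out["n_mitotic"] = n_mit
    if n_mit < min_cells:
        out.update(
            hyper_fraction_of_mitotic=np.nan,
            ph2ax_pos_mitotic_3n6n=np.nan, ph2ax_pos_mitotic_hyper=np.nan,
        )
        return out

    mit_idx = mit.index[mit]
    hyper = labels.loc[mit_idx, "cycle"] == "HYPER"
    out["hyper_fraction_of_mitotic"] = float(hyper.mean())
    if "pos_ph2ax" in labels.columns:
        ph2 = labels.loc[mit_idx, "pos_ph2ax"]
        for name, sel in (("3n6n", ~hyper), ("hyper", hyper)):
            out[f"ph2ax_pos_mitotic_{name}"] = (
                float(ph2[sel].mean()) if int(sel.sum()) >= min_cells else np.nan
            )
    return out


# ---------------------------------------------------------------------------
# dose response

@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit: y = bottom + (top-bottom)/(1+(d/ic50)^hill)."""

    top: float
    bottom: float
    hill: float
    ic50: float
    rss: float
    n_points: int

    def predict(self, dose) -> np.ndarray:
        return _four_pl(np.asarray(dose, float), self.top, self.bottom,
                        self.hill, np.log(self.ic50))

    def icq(self, q: float) -> float:
        """Dose giving q% inhibition: ICq = IC50 * (q/(100-q))^(1/hill)."""
        if not 0 < q < 100:
            raise KineticsError("q must be in (0, 100)")
        return float(self.ic50 * (q / (100.0 - q)) ** (1.0 / self.hill))


def _four_pl(dose, top, bottom, hill, log_ic50):
    dose = np.asarray(dose, dtype=np.float64)
    ic50 = np.exp(log_ic50)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_dose_response(doses, survival) -> DoseResponseFit:
    """Least-squares 4PL fit of normalized survival against dose (µM).

    Requires at least four distinct doses including a vehicle (0) anchor.
    """
    d = np.asarray(doses, dtype=np.float64)
    y = np.asarray(survival, dtype=np.float64)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(np.unique(d)) < 4 or 0.0 not in d:
        raise KineticsError("need >= 4 distinct doses including 0")

    top0 = float(np.mean(y[d == 0]))
    bottom0 = float(np.min(y))
    pos = np.unique(d[d > 0])
    # initial ic50: dose whose mean response is nearest half-maximal
    half = bottom0 + 0.5 * (top0 - bottom0)
    means = np.array([np.mean(y[d == dd]) for dd in pos])
    ic0 = float(pos[np.argmin(np.abs(means - half))])
    p0 = [top0, bottom0, 1.0, np.log(max(ic0, 1e-6))]
    try:
        popt, _ = curve_fit(_four_pl, d, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(f"dose-response fit did not converge: {exc}") from exc
    top, bottom, hill, log_ic50 = popt
    if hill < 0:  # equivalent curve with flipped asymptotes
        top, bottom, hill = bottom, top, -hill
    resid = y - _four_pl(d, top, bottom, hill, log_ic50)
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), hill=float(hill),
        ic50=float(np.exp(log_ic50)), rss=float(np.sum(resid**2)),
        n_points=int(len(d)),
    )


# ---------------------------------------------------------------------------
# regrowth

def quantify_regrowth(
    well_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    well_area: float,
) -> pd.DataFrame:
    """Regrowth endpoints for a plate of whole-well scans.

    ``well_tables`` maps well id → (records, labels).  Only viable
    (propidium-iodide-excluded, non-debris) nuclei count.  covered_fraction =
    summed nuclear area / well area; ``normalized_growth`` scales each well's
    covered area to the well with the largest growth (max = 1.0).
    """
    if well_area <= 0:
        raise KineticsError("well_area must be > 0")
    rows = []
    for well, (records, labels) in well_tables.items():
        idx = _viable(records, labels)
        covered = float(records.loc[idx, "area"].sum())
        rows.append({"well": well, "n_viable": int(len(idx)),
                     "covered_area": covered,
                     "covered_fraction": covered / well_area})
    df = pd.DataFrame(rows)
    max_cov = df["covered_area"].max() if len(df) else 0.0
    df["normalized_growth"] = df["covered_area"] / max_cov if max_cov > 0 else np.nan
    return df


def centroid_map(records: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Centroid (x, y) of every viable nucleus, for regrowth plotting."""
    idx = _viable(records, labels)
    cols = [c for c in ("well", "centroid_x", "centroid_y") if c in records.columns]
    return records.loc[idx, cols].reset_index(drop=True)
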