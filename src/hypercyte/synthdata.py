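"""Ground-truthed synthetic single-cell populations, image fields and movies.

The generator emulates the statistical structure of a near-triploid ovarian
carcinoma line imaged by high-content confocal microscopy: the G1 peak of the
integrated Hoechst (DNA content) histogram sits at 3N and the G2 peak at 6N;
an EdU-positive S-phase arc spans the two; a hyperploid class carries >6N DNA
and a correspondingly larger nucleus (area scales as a power of relative
ploidy, linear by default so ~12N cells are ~4-fold larger than G1 cells);
viability classes are encoded as propidium-iodide / caspase-indicator
positivity; antibody markers are two-component (negative/positive) mixtures.

Every cell carries a ground-truth row (class, viability, DNA, area, marker
states) so downstream gating, segmentation and tracking can be scored against
known answers.  All draws are deterministic given the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from scipy.ndimage import gaussian_filter

from . import ANTIBODY_CHANNELS, CHANNELS, CYCLE_CLASSES, VIABILITY_CLASSES

# fixed offsets deriving per-stage random streams from the master seed
_SEED_OFFSET_POPULATION = 0
_SEED_OFFSET_RENDER = 1000
_SEED_OFFSET_MOVIE = 2000

_FRACTION_TOL = 1e-9


class SpecError(ValueError):
    """Raised when a population/imaging spec violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed in a field without overlap."""


@dataclass(frozen=True)
class MarkerModel:
    """Two-component intensity model for one marker channel.

    Fluorescence intensities are strictly positive, so each component is a
    log-normal moment-matched to the stated linear-scale mean and SD;
    ``pos_fraction`` is the marginal probability of the positive state for
    markers whose state is not tied to cell-cycle class or viability.
    """

    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float
    pos_fraction: float = 0.0

    @staticmethod
    def _lognormal(rng, mean, sd, size):
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - 0.5 * sigma2
        return rng.lognormal(mu, math.sqrt(sigma2), size=size)

    def draw(self, rng: np.random.Generator, positive: np.ndarray) -> np.ndarray:
        out = self._lognormal(rng, self.neg_mean, self.neg_sd, positive.shape)
        pos = self._lognormal(rng, self.pos_mean, self.pos_sd, positive.shape)
        out[positive] = pos[positive]
        return out


def default_marker_models() -> dict[str, MarkerModel]:
    return {
        "pi": MarkerModel(20.0, 5.0, 200.0, 40.0),
        "caspase": MarkerModel(15.0, 4.0, 150.0, 30.0),
        "edu": MarkerModel(10.0, 3.0, 120.0, 25.0),
        "ph3": MarkerModel(10.0, 3.0, 100.0, 20.0),
        "ph2ax": MarkerModel(30.0, 8.0, 300.0, 60.0, pos_fraction=0.0),
        "pchk1": MarkerModel(50.0, 10.0, 150.0, 30.0, pos_fraction=0.0),
        "ki67": MarkerModel(20.0, 5.0, 180.0, 35.0, pos_fraction=0.7),
        "cparp": MarkerModel(25.0, 6.0, 250.0, 50.0, pos_fraction=0.0),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of one synthetic well population.

    DNA content is in arbitrary integrated-fluorescence units anchored at
    ``dna_anchor_3n`` (the G1 peak of the near-triploid line); nuclear areas
    are px²; ``hyper_ploidy_range`` is in multiples of 3N and must exceed 2
    so hyperploid DNA is strictly >6N.
    """

    n_cells: int = 2000
    class_fractions: dict = field(
        default_factory=lambda: {"G1": 0.55, "S": 0.25, "G2": 0.18, "HYPER": 0.02}
    )
    dna_anchor_3n: float = 300.0
    dna_cv: float = 0.06
    area_anchor_g1: float = 400.0
    area_exponent: float = 1.0
    area_cv: float = 0.08
    hyper_ploidy_range: tuple[float, float] = (2.2, 4.0)
    viability_fractions: dict = field(
        default_factory=lambda: {
            "VIABLE": 0.90,
            "NECROTIC": 0.04,
            "EARLY_APOPTOTIC": 0.03,
            "LATE_APOPTOTIC": 0.03,
        }
    )
    marker_models: dict = field(default_factory=default_marker_models)
    #: fraction of extra records that are sub-G1 DNA debris fragments
    fragment_fraction: float = 0.0
    #: marginal probability of the mitotic (pH3-positive) state
    mitotic_fraction: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise SpecError("n_cells must be positive")
        for name, fracs, keys in (
            ("class_fractions", self.class_fractions, CYCLE_CLASSES),
            ("viability_fractions", self.viability_fractions, VIABILITY_CLASSES),
        ):
            vals = [float(fracs.get(k, 0.0)) for k in keys]
            if any(v < 0 for v in vals):
                raise SpecError(f"{name} must be non-negative")
            if abs(sum(vals) - 1.0) > _FRACTION_TOL:
                raise SpecError(f"{name} must sum to 1 (got {sum(vals)!r})")
        if self.dna_cv <= 0:
            raise SpecError("dna_cv must be > 0")
        lo, hi = self.hyper_ploidy_range
        if not (2.0 < lo <= hi):
            raise SpecError("hyper_ploidy_range must lie entirely above 2.0")
        if not 0.0 <= self.fragment_fraction < 1.0:
            raise SpecError("fragment_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ImagingSpec:
    """Rendering / acquisition geometry for synthetic fields and movies."""

    field_size: tuple[int, int] = (512, 512)
    n_fields: int = 12
    psf_sigma: float = 1.0
    background_level: float = 2.0
    background_sd: float = 0.5
    photon_noise: bool = False
    pixel_saturation: float = 65535.0
    frame_interval_min: float = 30.0
    n_frames: int = 21

    def validate(self) -> None:
        if min(self.field_size) <= 0:
            raise SpecError("field_size must be positive")
        if self.psf_sigma < 0:
            raise SpecError("psf_sigma must be >= 0")
        if self.frame_interval_min <= 0:
            raise SpecError("frame_interval must be > 0")


def _assign_classes(rng: np.random.Generator, n: int, fractions: dict,
                    order: tuple[str, ...]) -> np.ndarray:
    """Per-cell class from one uniform draw mapped through the cumulative
    fractions taken in the fixed order ``order`` (the documented seed policy)."""
    probs = np.array([float(fractions.get(k, 0.0)) for k in order])
    edges = np.cumsum(probs)
    u = rng.random(n)
    idx = np.searchsorted(edges, u, side="right")
    idx = np.minimum(idx, len(order) - 1)
    return np.asarray(order, dtype=object)[idx]


def generate_population(
    spec: PopulationSpec,
    *,
    well: str = "A01",
    fld: int = 0,
    day: int = 1,
    condition: float = 0.0,
    id_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one well population; returns ``(truth, records)`` tables.

    ``truth`` carries ground-truth class / viability / DNA / area / marker
    states per cell; ``records`` is the per-nucleus feature table the gating
    engine consumes (same schema as :func:`hypercyte.nucleiseg.extract_features`
    output), with ``integrated_hoechst = area × mean_hoechst`` exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + _SEED_OFFSET_POPULATION)
    n = spec.n_cells
    a3 = spec.dna_anchor_3n

    cls = _assign_classes(rng, n, spec.class_fractions, CYCLE_CLASSES)
    viab = _assign_classes(rng, n, spec.viability_fractions, VIABILITY_CLASSES)

    dna = np.empty(n)
    noise = rng.normal(1.0, spec.dna_cv, size=n)
    g1, s, g2, hyp = (cls == c for c in CYCLE_CLASSES)
    dna[g1] = a3 * noise[g1]
    dna[g2] = 2.0 * a3 * noise[g2]
    dna[s] = rng.uniform(a3, 2.0 * a3, size=int(s.sum())) * noise[s]
    lo, hi = spec.hyper_ploidy_range
    dna[hyp] = a3 * rng.uniform(lo, hi, size=int(hyp.sum())) * noise[hyp]
    dna = np.clip(dna, 1e-6, None)

    rel_ploidy = dna / a3
    # multiplicative lognormal noise with unit mean so area ratios are unbiased
    sigma = math.sqrt(math.log(1.0 + spec.area_cv**2))
    area_noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    area = spec.area_anchor_g1 * rel_ploidy**spec.area_exponent * area_noise
    area = np.clip(area, 4.0, None)

    mitotic = rng.random(n) < spec.mitotic_fraction

    state = {}
    state["edu"] = cls == "S"
    state["ph3"] = mitotic
    state["pi"] = np.isin(viab, ["NECROTIC", "LATE_APOPTOTIC"])
    state["caspase"] = np.isin(viab, ["EARLY_APOPTOTIC", "LATE_APOPTOTIC"])
    for m in ("ph2ax", "pchk1", "ki67", "cparp"):
        model = spec.marker_models[m]
        state[m] = rng.random(n) < model.pos_fraction

    intensity = {
        m: spec.marker_models[m].draw(rng, state[m])
        for m in spec.marker_models
    }
    # cleaved-PARP positivity co-varies on the N:C ratio axis
    nc_cparp = np.clip(rng.normal(1.0, 0.15, size=n), 0.2, None)
    nc_cparp[state["cparp"]] = np.clip(
        rng.normal(3.0, 0.5, size=int(state["cparp"].sum())), 1.2, None
    )

    ids = np.arange(id_offset, id_offset + n)
    truth = pd.DataFrame(
        {
            "cell_id": ids,
            "true_class": cls,
            "true_viability": viab,
            "true_dna": dna,
            "true_area": area,
        }
    )
    for m in sorted(state):
        truth[f"state_{m}"] = state[m]

    records = pd.DataFrame(
        {
            "cell_id": ids,
            "well": well,
            "field": fld,
            "day": day,
            "condition": condition,
            "centroid_x": rng.uniform(0, 2048, size=n),
            "centroid_y": rng.uniform(0, 2048, size=n),
            "area": area,
            "mean_hoechst": dna / area,
        }
    )
    records["integrated_hoechst"] = records["area"] * records["mean_hoechst"]
    for m in ("pi", "caspase", "edu", "ph3", "ph2ax", "pchk1", "ki67", "cparp"):
        records[f"mean_{m}"] = intensity[m]
    records["nc_ratio_cparp"] = nc_cparp
    records["cyto_ring_mean_cparp"] = records["mean_cparp"] / nc_cparp

    if spec.fragment_fraction > 0:
        n_frag = int(round(n * spec.fragment_fraction / (1 - spec.fragment_fraction)))
        ft, fr = _generate_fragments(
            spec, n_frag, rng, well=well, fld=fld, day=day,
            condition=condition, id_offset=id_offset + n,
        )
        truth = pd.concat([truth, ft], ignore_index=True)
        records = pd.concat([records, fr], ignore_index=True)

    return truth, records


def _generate_fragments(spec, n_frag, rng, *, well, fld, day, condition, id_offset):
    """Sub-G1 DNA debris: fragments at ~5% of the G1 DNA content."""
    dna = np.clip(
        0.05 * spec.dna_anchor_3n * rng.normal(1.0, spec.dna_cv, size=n_frag),
        1e-6, None,
    )
    area = np.clip(0.08 * spec.area_anchor_g1 * rng.normal(1.0, 0.2, size=n_frag), 2.0, None)
    ids = np.arange(id_offset, id_offset + n_frag)
    truth = pd.DataFrame(
        {
            "cell_id": ids,
            "true_class": "DEBRIS",
            "true_viability": "NECROTIC",
            "true_dna": dna,
            "true_area": area,
        }
    )
    for m in sorted(spec.marker_models):
        truth[f"state_{m}"] = False
    records = pd.DataFrame(
        {
            "cell_id": ids,
            "well": well,
            "field": fld,
            "day": day,
            "condition": condition,
            "centroid_x": rng.uniform(0, 2048, size=n_frag),
            "centroid_y": rng.uniform(0, 2048, size=n_frag),
            "area": area,
            "mean_hoechst": dna / area,
        }
    )
    records["integrated_hoechst"] = records["area"] * records["mean_hoechst"]
    for m in ("pi", "caspase", "edu", "ph3", "ph2ax", "pchk1", "ki67", "cparp"):
        model = spec.marker_models[m]
        records[f"mean_{m}"] = model.draw(rng, np.zeros(n_frag, dtype=bool))
    records["nc_ratio_cparp"] = np.clip(rng.normal(1.0, 0.15, size=n_frag), 0.2, None)
    records["cyto_ring_mean_cparp"] = records["mean_cparp"] / records["nc_ratio_cparp"]
    return truth, records


# ---------------------------------------------------------------------------
# field rendering

def _ellipse_pixels(rng, cy, cx, area, axis_ratio, shape, lobed=False):
    """Pixel coordinates of an ellipse (or 2-3 overlapping lobes) of ~area px²."""
    if not lobed:
        a = math.sqrt(area / (math.pi * axis_ratio))
        b = axis_ratio * a
        rot = rng.uniform(0, math.pi)
        rr, cc = _draw_ellipse(cy, cx, a, b, shape=shape, rotation=rot)
        return rr, cc
    n_lobes = int(rng.integers(2, 4))
    sub = area / n_lobes * 1.3  # lobes overlap, union ≈ area
    pix = set()
    for _ in range(n_lobes):
        a = math.sqrt(sub / (math.pi * axis_ratio))
        b = axis_ratio * a
        dy, dx = rng.normal(0, 0.5 * a, size=2)
        rot = rng.uniform(0, math.pi)
        rr, cc = _draw_ellipse(cy + dy, cx + dx, a, b, shape=shape, rotation=rot)
        pix.update(zip(rr.tolist(), cc.tolist()))
    if not pix:
        return np.array([], dtype=int), np.array([], dtype=int)
    rr, cc = np.array(sorted(pix)).T
    return rr, cc


def _place_centers(rng, n, shape, radii, max_tries=3000):
    """Rejection-sample non-overlapping centers; radii are bounding radii."""
    centers = np.empty((n, 2))
    placed_r = np.empty(n)
    for i in range(n):
        r = radii[i]
        for attempt in range(max_tries):
            cy = rng.uniform(r + 1, shape[0] - r - 1)
            cx = rng.uniform(r + 1, shape[1] - r - 1)
            if i == 0:
                break
            d = np.hypot(centers[:i, 0] - cy, centers[:i, 1] - cx)
            if np.all(d > placed_r[:i] + r + 2.0):
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} in field {shape} "
                "without overlap; reduce density or enlarge the field"
            )
        centers[i] = (cy, cx)
        placed_r[i] = r
    return centers


def render_field(
    cells: pd.DataFrame,
    imaging: ImagingSpec,
    seed: int,
) -> tuple[dict[str, np.ndarray], np.ndarray, pd.DataFrame]:
    """Render one multi-channel field from a truth(+record) table.

    ``cells`` needs ``true_dna`` and ``true_area`` columns; any ``mean_<ch>``
    column present is rendered as a uniform nuclear intensity in that channel,
    and a dim cytoplasmic halo is added where ``nc_ratio_<ch>`` exists.
    The noise-free Hoechst channel conserves each nucleus's summed intensity
    (= true_dna) exactly by construction.

    Returns ``(channel images, uint16 label mask, placed)`` where ``placed``
    is a copy of ``cells`` with ``mask_label``, ``centroid_y``, ``centroid_x``
    filled in for the rendered positions.
    """
    imaging.validate()
    rng = np.random.default_rng(seed + _SEED_OFFSET_RENDER)
    shape = tuple(imaging.field_size)
    n = len(cells)
    labels = np.zeros(shape, dtype=np.uint16)

    chans = ["hoechst"] + [
        c for c in CHANNELS if c != "hoechst" and f"mean_{c}" in cells.columns
    ]
    images = {c: np.zeros(shape, dtype=np.float64) for c in chans}

    placed = cells.reset_index(drop=True).copy()
    if n:
        areas = placed["true_area"].to_numpy(float)
        # bounding radius covers axis-ratio elongation plus a margin; the
        # cytoplasmic halo may abut neighbors, as real cytoplasm does
        radii = 1.35 * np.sqrt(areas / math.pi)
        order = np.argsort(-areas)  # large first eases packing
        centers = np.empty((n, 2))
        centers[order] = _place_centers(rng, n, shape, radii[order])

        mask_label = np.zeros(n, dtype=np.uint16)
        for i in range(n):
            row = placed.iloc[i]
            cy, cx = centers[i]
            lobed = str(row.get("true_class", "")) == "HYPER"
            q = rng.uniform(0.7, 0.95)
            rr, cc = _ellipse_pixels(rng, cy, cx, areas[i], q, shape, lobed=lobed)
            if len(rr) == 0:
                continue
            lab = i + 1
            labels[rr, cc] = lab
            mask_label[i] = lab
            images["hoechst"][rr, cc] = row["true_dna"] / len(rr)
            for c in chans[1:]:
                images[c][rr, cc] = row[f"mean_{c}"]
                nc_col = f"nc_ratio_{c}"
                if nc_col in placed.columns and np.isfinite(row[nc_col]) and row[nc_col] > 0:
                    hr, hc = _draw_ellipse(
                        cy, cx, 1.6 * math.sqrt(areas[i] / math.pi),
                        1.6 * math.sqrt(areas[i] / math.pi), shape=shape,
                    )
                    halo = np.zeros(shape, dtype=bool)
                    halo[hr, hc] = True
                    halo[labels > 0] = False
                    images[c][halo] = row[f"mean_{c}"] / row[nc_col]
        placed["mask_label"] = mask_label
        placed["centroid_y"] = centers[:, 0]
        placed["centroid_x"] = centers[:, 1]

    for c in chans:
        img = images[c]
        if imaging.psf_sigma > 0:
            img = gaussian_filter(img, imaging.psf_sigma)
        if imaging.photon_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        img = img + imaging.background_level
        if imaging.background_sd > 0:
            img = img + rng.normal(0.0, imaging.background_sd, size=shape)
        images[c] = np.clip(img, 0.0, imaging.pixel_saturation)

    return images, labels, placed


def simulate_plate(
    base_spec: PopulationSpec,
    *,
    conditions: tuple[float, ...] = (0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0),
    days: tuple[int, ...] = (1,),
    wells_per_condition: int = 3,
    n_control_cells: int = 1500,
    ic50: float = 5.0,
    hill: float = 1.5,
    floor: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a treated multi-well plate as concatenated truth/record tables.

    Per-well viable cell numbers follow a four-parameter logistic survival
    curve of the drug concentration (µM); with dose, the class mix shifts
    from the untreated profile toward a G2-arrest/hyperploid-enriched
    profile and the non-viable fraction rises — the concentration- and
    time-dependent structure the downstream endpoints quantify.
    """
    rng = np.random.default_rng(seed + 7 * _SEED_OFFSET_POPULATION + 17)
    treated_mix = {"G1": 0.28, "S": 0.05, "G2": 0.37, "HYPER": 0.30}
    truths, recs = [], []
    offset = 0
    widx = 0
    for day in days:
        for cond in conditions:
            w = cond**hill / (cond**hill + ic50**hill) if cond > 0 else 0.0
            surv = floor + (1.0 - floor) / (1.0 + (cond / ic50) ** hill if cond > 0 else 1.0)
            mix = {
                k: (1 - w) * base_spec.class_fractions[k] + w * treated_mix[k]
                for k in CYCLE_CLASSES
            }
            tot = sum(mix.values())
            mix = {k: v / tot for k, v in mix.items()}
            viab = dict(base_spec.viability_fractions)
            shift = 0.25 * w
            viab["VIABLE"] = max(viab["VIABLE"] - shift, 0.2)
            rest = 1.0 - viab["VIABLE"]
            others = ["NECROTIC", "EARLY_APOPTOTIC", "LATE_APOPTOTIC"]
            base_rest = sum(base_spec.viability_fractions[o] for o in others)
            for o in others:
                viab[o] = rest * base_spec.viability_fractions[o] / base_rest
            for _ in range(wells_per_condition):
                n = max(int(rng.normal(surv * n_control_cells, 0.03 * n_control_cells)), 20)
                well = f"{chr(ord('A') + widx // 12)}{widx % 12 + 1:02d}"
                widx += 1
                spec = replace(
                    base_spec,
                    n_cells=n,
                    class_fractions=mix,
                    viability_fractions=viab,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                t, r = generate_population(
                    spec, well=well, day=day, condition=cond, id_offset=offset
                )
                offset += len(t)
                truths.append(t)
                recs.append(r)
    return pd.concat(truths, ignore_index=True), pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# time-lapse simulation

_EVENT_KINDS = ("division", "catastrophe", "slippage", "nonmitotic_death")


def simulate_timelapse(
    spec: PopulationSpec,
    imaging: ImagingSpec,
    event_rates: dict[str, float] | None = None,
    *,
    forced_events: dict[str, int] | None = None,
    motion_sd: float = 2.0,
    min_separation: float = 24.0,
    contact_scale: float = 0.9,
    seed: int | None = None,
    well: str = "A01",
    day: int = 1,
    condition: float = 0.0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate a nuclear time-lapse movie as per-frame record tables.

    Events: DIVISION replaces a nucleus with two nearby daughters (half DNA
    each); mitotic catastrophe and non-mitotic DEATH turn the nucleus
    propidium-iodide-positive before it disappears; SLIPPAGE shows a transient
    two-lobe separation for two frames, then re-merges into one larger nucleus.
    Nuclei in mitosis carry a ``mitotic`` rounding flag on the entry frame.
    ``event_rates`` are per cell per hour; ``forced_events`` instead realizes
    exact event counts at random times/cells (events beyond capacity are
    dropped).  The event log records (frame, event, parent_id, child_ids,
    detail) with event ∈ {DIVISION, DEATH, SLIPPAGE}.
    """
    spec.validate()
    imaging.validate()
    if imaging.n_frames < 2:
        raise SpecError("n_frames must be >= 2")
    if event_rates:
        if any(v < 0 for v in event_rates.values()):
            raise SpecError("event rates must be >= 0")
        unknown = set(event_rates) - set(_EVENT_KINDS)
        if unknown:
            raise SpecError(f"unknown event kinds: {sorted(unknown)}")

    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master + _SEED_OFFSET_MOVIE)
    n_frames = imaging.n_frames
    dt_h = imaging.frame_interval_min / 60.0
    h, w = imaging.field_size

    truth, records = generate_population(
        replace(spec, seed=master), well=well, day=day, condition=condition
    )
    pi_model = spec.marker_models["pi"]

    # live-cell state; nuclei are solid objects, so initial positions keep a
    # minimum separation (rejection sampling)
    cells: dict[int, dict] = {}
    placed: list[tuple[float, float]] = []
    for _, r in records.iterrows():
        for _ in range(2000):
            y = rng.uniform(20, h - 20)
            x = rng.uniform(20, w - 20)
            if all(
                (y - py) ** 2 + (x - px) ** 2 >= min_separation**2
                for py, px in placed
            ):
                break
        else:
            raise PlacementError(
                f"cannot place {len(records)} nuclei at min separation "
                f"{min_separation} px in a {h}x{w} field"
            )
        placed.append((y, x))
        cells[int(r.cell_id)] = {
            "y": y,
            "x": x,
            "area": float(r.area),
            "dna": float(r.integrated_hoechst),
            "pi_pos": False,
            "mitotic": False,
            "program": None,  # (kind, phase, payload)
        }
    next_id = int(records.cell_id.max()) + 1

    # forced-event schedule: (frame, kind), resolved to a free cell at run time
    schedule: dict[int, list[str]] = {}
    if forced_events:
        last_start = max(1, n_frames - 6)  # leave room to resolve
        for kind, count in forced_events.items():
            if kind not in _EVENT_KINDS:
                raise SpecError(f"unknown event kind: {kind}")
            for f in rng.integers(1, last_start + 1, size=int(count)):
                schedule.setdefault(int(f), []).append(kind)

    log_rows: list[dict] = []
    frames: list[pd.DataFrame] = []

    def snapshot(f: int) -> pd.DataFrame:
        rows = []
        for cid, st in cells.items():
            mean_pi = float(
                np.clip(
                    rng.normal(
                        pi_model.pos_mean if st["pi_pos"] else pi_model.neg_mean,
                        pi_model.pos_sd if st["pi_pos"] else pi_model.neg_sd,
                    ),
                    1e-3, None,
                )
            )
            area = st["area"]
            rows.append(
                {
                    "cell_id": cid,
                    "well": well,
                    "day": day,
                    "condition": condition,
                    "frame": f,
                    "centroid_x": st["x"],
                    "centroid_y": st["y"],
                    "area": area,
                    "mean_hoechst": st["dna"] / area,
                    "integrated_hoechst": st["dna"],
                    "mean_pi": mean_pi,
                    "pi_positive": bool(st["pi_pos"]),
                    "mitotic": bool(st["mitotic"]),
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values("cell_id", ignore_index=True) if len(df) else df

    def start_program(cid: int, kind: str, f: int) -> None:
        st = cells[cid]
        st["program"] = {"kind": kind, "phase": 0, "pre_area": st["area"]}
        if kind in ("division", "catastrophe", "slippage"):
            st["mitotic"] = True
            st["area"] *= 0.75  # mitotic rounding: projected area drops
        if kind == "nonmitotic_death":
            st["pi_pos"] = True
            log_rows.append(
                {"frame": f, "event": "DEATH", "parent_id": cid,
                 "child_ids": [], "detail": "nonmitotic"}
            )

    def step_programs(f: int) -> None:
        nonlocal next_id
        for cid in list(cells):
            st = cells.get(cid)
            if st is None or st["program"] is None:
                continue
            prog = st["program"]
            kind, phase = prog["kind"], prog["phase"]
            if kind == "division":
                if phase == 0:
                    d_ids = [next_id, next_id + 1]
                    next_id += 2
                    for j, did in enumerate(d_ids):
                        off = 8.0 * (1 if j == 0 else -1)
                        ang = rng.uniform(0, math.pi)
                        cells[did] = {
                            "y": np.clip(st["y"] + off * math.sin(ang), 2, h - 2),
                            "x": np.clip(st["x"] + off * math.cos(ang), 2, w - 2),
                            "area": 0.55 * prog["pre_area"],
                            "dna": st["dna"] / 2.0,
                            "pi_pos": False,
                            "mitotic": False,
                            "program": None,
                        }
                    log_rows.append(
                        {"frame": f, "event": "DIVISION", "parent_id": cid,
                         "child_ids": d_ids, "detail": ""}
                    )
                    del cells[cid]
            elif kind == "catastrophe":
                if phase == 0:
                    st["pi_pos"] = True
                    st["area"] = 0.6 * prog["pre_area"]  # fragmentation
                    st["mitotic"] = False
                    prog["phase"] = 1
                    log_rows.append(
                        {"frame": f, "event": "DEATH", "parent_id": cid,
                         "child_ids": [], "detail": "catastrophe"}
                    )
                else:
                    del cells[cid]
            elif kind == "slippage":
                if phase == 0:
                    t_ids = [next_id, next_id + 1]
                    next_id += 2
                    for j, tid in enumerate(t_ids):
                        off = 6.0 * (1 if j == 0 else -1)
                        cells[tid] = {
                            "y": st["y"] + off * 0.3,
                            "x": st["x"] + off,
                            "area": 0.55 * prog["pre_area"],
                            "dna": st["dna"] / 2.0,
                            "pi_pos": False,
                            "mitotic": False,
                            "program": {"kind": "slip_lobe", "phase": 0,
                                        "pre_area": prog["pre_area"],
                                        "sibling": t_ids[1 - j],
                                        "primary": j == 0,
                                        "parent_dna": st["dna"]},
                        }
                    log_rows.append(
                        {"frame": f, "event": "SLIPPAGE", "parent_id": cid,
                         "child_ids": [], "detail": ""}
                    )
                    del cells[cid]
            elif kind == "slip_lobe":
                if phase == 0:
                    prog["phase"] = 1  # lobes drift one more frame
                elif prog["primary"]:
                    # re-merge: primary lobe becomes the large lobated nucleus
                    sib = prog["sibling"]
                    sy, sx = (cells[sib]["y"], cells[sib]["x"]) if sib in cells else (st["y"], st["x"])
                    st["y"] = 0.5 * (st["y"] + sy)
                    st["x"] = 0.5 * (st["x"] + sx)
                    st["area"] = 1.45 * prog["pre_area"]
                    st["dna"] = prog["parent_dna"]
                    st["program"] = None
                    cells.pop(sib, None)

            # non-mitotic death: remove one frame after PI onset
            if kind == "nonmitotic_death":
                if phase == 0:
                    prog["phase"] = 1
                else:
                    del cells[cid]

    frames.append(snapshot(0))
    for f in range(1, n_frames):
        # resolve multi-frame programs first, then new events, then motion
        step_programs(f)

        busy = {cid for cid, st in cells.items() if st["program"] is not None}
        free = [cid for cid in cells if cid not in busy and not cells[cid]["pi_pos"]]
        if forced_events:
            for kind in schedule.get(f, []):
                if not free:
                    break
                cid = free.pop(int(rng.integers(len(free))))
                start_program(cid, kind, f)
        elif event_rates and f <= n_frames - 5:
            # no initiations in the last frames: every program resolves
            # within the recording, keeping the event log count-consistent
            for cid in list(free):
                for kind in _EVENT_KINDS:
                    p = event_rates.get(kind, 0.0) * dt_h
                    if p > 0 and rng.random() < p:
                        free.remove(cid)
                        start_program(cid, kind, f)
                        break

        # random-walk motion with excluded volume: a step that would bring
        # two nuclei closer than contact_scale x the sum of their radii is
        # rejected (confluent cells jostle but do not interpenetrate)
        ids = list(cells)
        pos = np.array([(cells[c]["y"], cells[c]["x"]) for c in ids])
        radii = np.sqrt(np.array([cells[c]["area"] for c in ids]) / math.pi)
        for idx, cid in enumerate(ids):
            st = cells[cid]
            ny = float(np.clip(st["y"] + rng.normal(0, motion_sd), 2, h - 2))
            nx = float(np.clip(st["x"] + rng.normal(0, motion_sd), 2, w - 2))
            dd = np.hypot(pos[:, 0] - ny, pos[:, 1] - nx)
            limit = contact_scale * (radii + radii[idx])
            limit[idx] = -1.0
            if np.all(dd >= limit):
                st["y"], st["x"] = ny, nx
                pos[idx] = (ny, nx)

        frames.append(snapshot(f))

    event_log = pd.DataFrame(
        log_rows, columns=["frame", "event", "parent_id", "child_ids", "detail"]
    )
    return frames, event_log
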