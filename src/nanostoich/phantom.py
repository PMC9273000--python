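"""Synthetic NanoSIMS phantoms of drug-treated cells on resin sections.

The phantom emulates the statistical structure of semi-thin-section ion
images of cultured cancer cells exposed to a ¹⁵N-labelled platinum drug:
a raster of a few hundred pixels per side covering a 32–40 μm field, a
handful of roughly circular cells, each with cytoplasm, nucleus
(excluding the nucleolus), a C/N/P/S-rich nucleolus, an uneven
phosphorus-rich chromatin rim along the inner nuclear membrane, and
sulfur-rich cytoplasmic aggregates.  Every pixel count is drawn
independently from a Poisson distribution whose mean is the compartment's
expected count rate for that channel — detector shot noise is the only
noise source modelled (no dead time, QSA or beam drift, and no depth
profiling: each acquisition is a single accumulated 2-D frame).

Drug accumulation adds ¹⁹⁴Pt⁻ counts and, through the retained ammine
ligands, ¹⁵N-enriched nitrogen that enters only the CN⁻ channels.  The
per-compartment ¹²C¹⁵N⁻/¹²C¹⁴N⁻ rate split realises the two-endpoint
mixing abundance ``a = a_ctr + x·(a_cddp − a_ctr)`` where ``x`` is the
compartment's true label fraction.  Relative sensitivity factors (RSFs)
map atom amounts to count rates and are known by construction, which is
what makes the phantom's stoichiometry exactly recoverable — on real
samples SIMS remains semi-quantitative.

The nitrogen run can be translated by a configurable whole-pixel
inter-run shift, emulating stage drift between the sequential platinum
and nitrogen-isotope acquisitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .channels import DEFAULT_CHANNELS, channel
from .errors import ConfigurationError
from .io import AcquisitionStack, IonCountMap
from .roi import CompartmentMask

#: Terrestrial natural abundance of ¹⁵N.
NATURAL_15N_ABUNDANCE = 0.003676

COMPARTMENT_LABELS = {1: "cytoplasm", 2: "nucleus", 3: "nucleolus",
                      4: "chromatin", 5: "aggregate"}

#: Default expected counts per pixel under zero drug, per compartment.
#: CN rates are given as a total and split between ¹²C¹⁴N⁻/¹²C¹⁵N⁻ by the
#: control abundance.  Chosen so ROI sums span 10³–10⁶ counts on a
#: 256–512 px grid, the regime where per-mil isotope precision is reached.
DEFAULT_CN_YIELD = {"background": 20.0, "cytoplasm": 1000.0, "nucleus": 1400.0,
                    "nucleolus": 2600.0, "chromatin": 2000.0, "aggregate": 1200.0}
DEFAULT_YIELDS = {
    "12C2": {"background": 50.0, "cytoplasm": 2200.0, "nucleus": 2400.0,
             "nucleolus": 3200.0, "chromatin": 2600.0, "aggregate": 2300.0},
    "31P": {"background": 0.5, "cytoplasm": 20.0, "nucleus": 60.0,
            "nucleolus": 150.0, "chromatin": 180.0, "aggregate": 30.0},
    "34S": {"background": 0.5, "cytoplasm": 25.0, "nucleus": 30.0,
            "nucleolus": 120.0, "chromatin": 35.0, "aggregate": 140.0},
    "19F": {"background": 0.2, "cytoplasm": 5.0, "nucleus": 2.0,
            "nucleolus": 2.0, "chromatin": 2.0, "aggregate": 80.0},
    "194Pt": {c: 0.0 for c in DEFAULT_CN_YIELD},
}

#: Default drug accumulation: expected extra ¹⁹⁴Pt⁻ counts per pixel per
#: μM exposure.  At 150 μM these give 1–5 counts/px, matching the
#: colour-scale maxima of published ¹⁹⁴Pt⁻ maps, and keep the true label
#: fraction below 0.4 per mil everywhere.
DEFAULT_ACCUMULATION = {"background": 0.0, "cytoplasm": 0.008,
                        "nucleus": 0.006, "nucleolus": 0.03,
                        "chromatin": 0.012, "aggregate": 0.02}


@dataclass
class PhantomConfig:
    """Full description of one synthetic acquisition pair.

    Lengths are in μm, times in ms, count rates in expected counts per
    pixel.  ``drug_load`` is the expected ¹⁹⁴Pt⁻ counts per pixel added by
    the drug in each compartment; ``ligand_retention`` is the number of
    nitrogen atoms retained per accumulated Pt atom (2 for the intact
    cis-diammine compound, lower after ligand cleavage, physically ≤ 3).
    ``rsf_pt`` and ``rsf_cn`` convert atom amounts (arbitrary common
    units) into ¹⁹⁴Pt⁻ and CN⁻ count rates; only their ratio matters.
    """

    grid: tuple[int, int] = (512, 512)
    pixel_size: float = 36.0 / 512      # μm; 36 μm field of view
    dwell_time: float = 250.0           # ms per pixel
    n_cells: int = 3
    cell_radius: float = 5.0            # μm
    nucleus_radius: float = 2.5         # μm
    nucleolus_radius: float = 0.8       # μm
    chromatin_rim_thickness: float = 0.45  # μm
    n_aggregates: int = 6               # per cell
    aggregate_radius: float = 0.4       # μm
    base_yields: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_YIELDS.items()})
    cn_yield: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CN_YIELD))
    drug_load: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in DEFAULT_CN_YIELD})
    ligand_retention: dict[str, float] = field(
        default_factory=lambda: {c: 2.0 for c in DEFAULT_CN_YIELD})
    rsf_pt: float = 90.0
    rsf_cn: float = 10.0
    a_cddp: float = 0.99                # ¹⁵N purity of the labelled drug
    a_ctr: float = NATURAL_15N_ABUNDANCE
    inter_run_shift: tuple[int, int] = (0, 0)
    exposure_concentration: float = 0.0  # μM, metadata only
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.a_cddp <= 1) or not (0 < self.a_ctr < 1):
            raise ConfigurationError("abundances must lie in (0, 1]")
        if self.a_ctr >= self.a_cddp:
            raise ConfigurationError("a_ctr must be smaller than a_cddp")
        if not (self.nucleolus_radius < self.nucleus_radius < self.cell_radius):
            raise ConfigurationError(
                "geometry must nest: nucleolus inside nucleus inside cell")
        if self.chromatin_rim_thickness >= self.nucleus_radius:
            raise ConfigurationError("chromatin rim thicker than the nucleus")
        if self.rsf_pt <= 0 or self.rsf_cn <= 0:
            raise ConfigurationError("sensitivity factors must be positive")
        for comp, nu in self.ligand_retention.items():
            if not (0 <= nu <= 3):
                raise ConfigurationError(
                    f"ligand_retention[{comp}]={nu} outside [0, 3]")
        for table in (self.cn_yield, self.drug_load):
            for comp, v in table.items():
                if v < 0:
                    raise ConfigurationError(f"negative rate for {comp}")

    # -- derived per-compartment truths ---------------------------------

    def true_label_fraction(self, comp: str) -> float:
        """Fraction of the compartment's nitrogen that is drug-derived."""
        endo_n = self.cn_yield[comp] / self.rsf_cn
        pt_atoms = self.drug_load[comp] / self.rsf_pt
        drug_n = self.ligand_retention[comp] * pt_atoms
        tot = endo_n + drug_n
        return drug_n / tot if tot > 0 else 0.0

    def true_pt_index(self, comp: str) -> float:
        """Expected value of the reference-normalised Pt/N index."""
        endo_n = self.cn_yield[comp] / self.rsf_cn
        pt_atoms = self.drug_load[comp] / self.rsf_pt
        tot = endo_n + self.ligand_retention[comp] * pt_atoms
        return (self.rsf_pt / self.rsf_cn) * pt_atoms / tot if tot > 0 else 0.0

    def channel_rates(self, comp: str) -> dict[str, float]:
        """Expected counts/pixel for every channel in one compartment."""
        x = self.true_label_fraction(comp)
        a = self.a_ctr + x * (self.a_cddp - self.a_ctr)
        pt_atoms = self.drug_load[comp] / self.rsf_pt
        cn_total = self.cn_yield[comp] + \
            self.rsf_cn * self.ligand_retention[comp] * pt_atoms
        rates = {ch: tbl[comp] for ch, tbl in self.base_yields.items()}
        rates["194Pt"] = rates.get("194Pt", 0.0) + self.drug_load[comp]
        rates["12C14N"] = (1.0 - a) * cn_total
        rates["12C15N"] = a * cn_total
        return rates

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid", "inter_run_shift"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the phantom actually contains, for parameter-recovery tests."""

    mask: CompartmentMask
    label_fraction: dict[str, float]      # compartment -> true x
    pt_index: dict[str, float]            # compartment -> true q
    stoichiometry: dict[str, float]       # compartment -> true N:Pt ratio
    inter_run_shift: tuple[int, int]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "label_fraction": self.label_fraction,
            "pt_index": self.pt_index,
            "stoichiometry": self.stoichiometry,
            "inter_run_shift": list(self.inter_run_shift),
        }, indent=1))
        return path


# ---------------------------------------------------------------------------
# geometry


def _place_cells(cfg: PhantomConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    rows, cols = cfg.grid
    r_px = cfg.cell_radius / cfg.pixel_size
    margin = r_px + 2
    if 2 * margin >= min(rows, cols):
        raise ConfigurationError(
            f"cell radius {cfg.cell_radius} μm does not fit the "
            f"{rows}x{cols} grid at {cfg.pixel_size:.4f} μm/px")
    if cfg.n_cells == 1:
        return [(rows / 2, cols / 2)]
    centers: list[tuple[float, float]] = []
    for _ in range(4000):
        cand = (rng.uniform(margin, rows - margin),
                rng.uniform(margin, cols - margin))
        if all(math.hypot(cand[0] - c[0], cand[1] - c[1]) >= 2 * r_px + 2
               for c in centers):
            centers.append(cand)
            if len(centers) == cfg.n_cells:
                return centers
    raise ConfigurationError(
        f"could not place {cfg.n_cells} non-overlapping cells on the grid")


def _build_mask(cfg: PhantomConfig, rng: np.random.Generator) -> CompartmentMask:
    """Compartment label image: one set of mutually exclusive ROIs per cell."""
    rows, cols = cfg.grid
    px = cfg.pixel_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    labels = np.zeros((rows, cols), dtype=np.int64)
    legend: dict[int, str] = {}
    roi_ids: dict[int, str] = {}

    centers = _place_cells(cfg, rng)
    next_label = 1
    for i, (cy, cx) in enumerate(centers, start=1):
        d = np.hypot(rr - cy, cc - cx) * px
        cell = d <= cfg.cell_radius
        nucleus = d <= cfg.nucleus_radius
        rim_inner = cfg.nucleus_radius - cfg.chromatin_rim_thickness
        # chromatin: uneven arcs along the inner nuclear membrane
        theta = np.arctan2(rr - cy, cc - cx)
        arc_mask = np.zeros((rows, cols), dtype=bool)
        for _ in range(3):
            start = rng.uniform(-math.pi, math.pi)
            width = rng.uniform(0.5, 1.4)
            dtheta = (theta - start) % (2 * math.pi)
            arc_mask |= dtheta < width
        chromatin = (d >= rim_inner) & nucleus & arc_mask
        # nucleolus: offset disc well inside the rim
        max_off = max(rim_inner - cfg.nucleolus_radius - 2 * px, 0.0)
        ang = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(0, max_off)
        no_cy = cy + off * math.sin(ang) / px
        no_cx = cx + off * math.cos(ang) / px
        nucleolus = np.hypot(rr - no_cy, cc - no_cx) * px <= cfg.nucleolus_radius
        nucleolus &= nucleus
        # aggregates: non-overlapping discs in the cytoplasm
        agg = np.zeros((rows, cols), dtype=bool)
        placed: list[tuple[float, float]] = []
        r_agg_px = cfg.aggregate_radius / px
        for _ in range(500):
            if len(placed) == cfg.n_aggregates:
                break
            rad = rng.uniform(cfg.nucleus_radius + 2 * cfg.aggregate_radius,
                              cfg.cell_radius - 1.5 * cfg.aggregate_radius)
            ang = rng.uniform(0, 2 * math.pi)
            ay = cy + rad * math.sin(ang) / px
            ax = cx + rad * math.cos(ang) / px
            if all(math.hypot(ay - p[0], ax - p[1]) > 2 * r_agg_px + 1
                   for p in placed):
                placed.append((ay, ax))
                agg |= np.hypot(rr - ay, cc - ax) * px <= cfg.aggregate_radius
        agg &= cell & ~nucleus

        comp_masks = {
            "cytoplasm": cell & ~nucleus & ~agg,
            "nucleus": nucleus & ~nucleolus & ~chromatin,
            "nucleolus": nucleolus,
            "chromatin": chromatin & ~nucleolus,
            "aggregate": agg,
        }
        for comp, m in comp_masks.items():
            labels[m] = next_label
            legend[next_label] = comp
            roi_ids[next_label] = f"c{i}_{comp}"
            next_label += 1
    return CompartmentMask(labels, legend, roi_ids)


# ---------------------------------------------------------------------------
# sampling


def _compartment_name_map(mask: CompartmentMask) -> np.ndarray:
    """Per-pixel compartment index into COMPARTMENT order (0=background)."""
    comp_index = {"background": 0, "cytoplasm": 1, "nucleus": 2,
                  "nucleolus": 3, "chromatin": 4, "aggregate": 5}
    lut = np.zeros(int(mask.labels.max()) + 1, dtype=np.int64)
    for lab, comp in mask.legend.items():
        lut[lab] = comp_index[comp]
    return lut[mask.labels]


def _sample_run(cfg: PhantomConfig, mask: CompartmentMask, run_type: str,
                seeds: Sequence[np.random.SeedSequence]) -> AcquisitionStack:
    comp_map = _compartment_name_map(mask)
    order = ["background", "cytoplasm", "nucleus", "nucleolus",
             "chromatin", "aggregate"]
    rates_by_comp = {c: cfg.channel_rates(c) for c in order}
    maps = {}
    for ch_label, ss in zip(DEFAULT_CHANNELS[run_type], seeds):
        rate_lut = np.array([rates_by_comp[c][ch_label] for c in order])
        lam = rate_lut[comp_map]
        rng = np.random.default_rng(ss)
        counts = rng.poisson(lam).astype(np.uint32)
        maps[ch_label] = IonCountMap(channel(ch_label), counts,
                                     cfg.pixel_size, cfg.dwell_time)
    return AcquisitionStack(
        sample_id=f"phantom_s{cfg.seed}",
        run_type=run_type,
        maps=maps,
        exposure_concentration=cfg.exposure_concentration,
        is_control=cfg.exposure_concentration == 0,
    )


def generate_phantom(cfg: PhantomConfig
                     ) -> tuple[AcquisitionStack, AcquisitionStack, GroundTruth]:
    """Generate one paired (pt_run, n_run) phantom with its ground truth.

    The geometry, and every channel of each run, draws from a dedicated
    stream spawned deterministically from ``cfg.seed``: an identical
    config yields bit-identical output.  The nitrogen run is sampled on
    geometry translated by ``cfg.inter_run_shift`` (background-filled),
    emulating stage drift between the sequential acquisitions.
    """
    root = np.random.SeedSequence(cfg.seed)
    n_pt = len(DEFAULT_CHANNELS["pt_run"])
    n_n = len(DEFAULT_CHANNELS["n_run"])
    children = root.spawn(1 + n_pt + n_n)
    geo_rng = np.random.default_rng(children[0])

    mask = _build_mask(cfg, geo_rng)
    pt_stack = _sample_run(cfg, mask, "pt_run", children[1:1 + n_pt])
    d_row, d_col = cfg.inter_run_shift
    n_mask = mask.shifted(int(d_row), int(d_col))
    n_stack = _sample_run(cfg, n_mask, "n_run", children[1 + n_pt:])

    comps = ["cytoplasm", "nucleus", "nucleolus", "chromatin", "aggregate"]
    truth = GroundTruth(
        mask=mask,
        label_fraction={c: cfg.true_label_fraction(c) for c in comps},
        pt_index={c: cfg.true_pt_index(c) for c in comps},
        stoichiometry={c: cfg.ligand_retention[c] for c in comps},
        inter_run_shift=(int(d_row), int(d_col)),
    )
    return pt_stack, n_stack, truth


AccumulationModel = Callable[[str, float], float]


def linear_accumulation(slopes: Mapping[str, float] | None = None) -> AccumulationModel:
    """Drug load proportional to exposure concentration, per compartment."""
    slopes = dict(DEFAULT_ACCUMULATION if slopes is None else slopes)

    def model(comp: str, concentration: float) -> float:
        return slopes.get(comp, 0.0) * concentration

    return model


def nested_exposure_series(
    base_config: PhantomConfig,
    concentrations: Sequence[float],
    accumulation_model: AccumulationModel | None = None,
) -> list[tuple[AcquisitionStack, AcquisitionStack, GroundTruth]]:
    """One phantom triple per exposure concentration.

    Each concentration receives its own deterministically derived seed
    (fields of different samples contain different cells) and a drug load
    from the accumulation model, which must be monotone non-decreasing in
    concentration for every compartment.
    """
    if len(concentrations) == 0:
        raise ConfigurationError("concentration list must not be empty")
    if any(c < 0 for c in concentrations):
        raise ConfigurationError("concentrations must be non-negative (μM)")
    model = accumulation_model or linear_accumulation()
    comps = list(base_config.drug_load)
    ordered = sorted(concentrations)
    for comp in comps:
        loads = [model(comp, c) for c in ordered]
        if any(b < a - 1e-12 for a, b in zip(loads, loads[1:])):
            raise ConfigurationError(
                f"accumulation model not monotone for compartment {comp}")

    children = np.random.SeedSequence(base_config.seed).spawn(len(concentrations))
    out = []
    for conc, child in zip(concentrations, children):
        cfg = replace(
            base_config,
            drug_load={comp: model(comp, conc) for comp in comps},
            exposure_concentration=float(conc),
            seed=int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31)),
        )
        out.append(generate_phantom(cfg))
    return out


# ---------------------------------------------------------------------------
# section-sampling geometry


def central_section_volume_fraction(thickness_um: float,
                                    diameter_um: float) -> float:
    """Fraction of a spherical cell's volume contained in a central slab.

    A semi-thin section of thickness ``t`` through the equator of a
    sphere of radius ``r`` has volume ``π·t·(r² − t²/12)``; dividing by
    the sphere volume ``(4/3)·π·r³`` gives the fraction of the cell a
    single section samples — the quantity that links per-section ion
    counts to per-cell analyte amounts.
    """
    if thickness_um <= 0 or diameter_um <= 0 or thickness_um > diameter_um:
        raise ValueError("need 0 < thickness ≤ diameter")
    r = diameter_um / 2.0
    t = thickness_um
    return (math.pi * t * (r ** 2 - t ** 2 / 12.0)) / ((4.0 / 3.0) * math.pi * r ** 3)
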