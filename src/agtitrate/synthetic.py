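"""Synthetic HSQC titration generator with known ground truth.

Stands in for raw spectra: emulates an 11-30 residue disordered peptide at
~1 mM titrated with Ag+ up to 8 molar equivalents, producing assigned
(1H,15N) peak lists per point.  Free-state amide shifts are drawn uniformly
from the random-coil window (1H 7.6-8.8, 15N 105-130 ppm); under fast
exchange each binding-site residue moves along a straight trajectory by
theta_site * (ddmax_H, ddmax_N) plus Gaussian shift noise.  Residues in
intermediate exchange additionally lose intensity through a Lorentzian-like
attenuation that bottoms out near half-saturation of their site.

Presets encode the published study conditions (concentrations, molar-ratio
grids, model families and central Kd values) for the SilE and SilB model
peptides and their mixture/competition assays.  Residue one-letter types
are a synthetic stand-in: only the functionally named residues (e.g. K82,
M83, R89, M90; R405-H408, M416-M419) are placed faithfully, the remaining
positions are filler and never enter any computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .equilibria import (
    SITE1,
    SITE2,
    IdenticalSitesModel,
    MixtureModel,
    OneSiteModel,
    SequentialTwoSiteModel,
    species_state,
)
from .peaklist import (
    DEFAULT_ALPHA,
    CSPProfile,
    Peak,
    PeakList,
    TitrationPoint,
    TitrationSeries,
    write_series,
)

__all__ = ["GroundTruth", "generate_series", "preset", "PRESETS"]

# free-state amide windows (ppm) for a disordered peptide
H_RANGE = (7.6, 8.8)
N_RANGE = (105.0, 130.0)
SIGMA_H = 0.002
SIGMA_N = 0.02
DDMAX_RANGE = (0.02, 0.25)       # combined-CSP saturation amplitude, site residues
BACKGROUND_DDMAX = (0.0, 0.005)  # non-site residues


@dataclass
class GroundTruth:
    """Everything needed to generate a titration series deterministically."""

    name: str
    model_family: str                      # one_site | identical_sites | sequential
    kds: tuple[float, ...]                 # mol/L
    receptor: str
    p_tot: float                           # mol/L
    ratios: tuple[float, ...]              # molar ratios, first must be 0
    residues: tuple[int, ...]
    res_types: dict[int, str]
    site_map: dict[int, str]               # site residues only
    intermediate: tuple[int, ...] = ()
    sigma_h: float = SIGMA_H
    sigma_n: float = SIGMA_N
    n_sites: int = 2
    seed: int = 0
    ddmax: dict[int, float] = field(default_factory=dict)  # optional fixed amplitudes

    def __post_init__(self) -> None:
        if self.ratios[0] != 0:
            raise ValueError("first molar ratio must be 0 (free state)")
        if any(k <= 0 for k in self.kds):
            raise ValueError("Kd's must be positive")
        if any(v < 0 for v in self.ddmax.values()):
            raise ValueError("amplitudes must be non-negative")

    def build_model(self):
        if self.model_family == "one_site":
            return OneSiteModel(kd=self.kds[0])
        if self.model_family == "identical_sites":
            return IdenticalSitesModel(kd=self.kds[0], n_sites=self.n_sites)
        if self.model_family == "sequential":
            return SequentialTwoSiteModel(kd1=self.kds[0], kd2=self.kds[1])
        raise ValueError(f"unknown model family {self.model_family!r}")


def _attenuation(theta: float, width: float = 0.15) -> float:
    """Lorentzian-like intensity attenuation, minimum 0.05 near theta = 0.5."""
    lor = 1.0 / (1.0 + ((theta - 0.5) / width) ** 2)
    return 0.05 + 0.95 * (1.0 - lor)


def generate_series(
    truth: GroundTruth, alpha: float = DEFAULT_ALPHA
) -> tuple[TitrationSeries, CSPProfile]:
    """Generate a noisy titration series plus the noiseless truth profile.

    Deterministic given ``truth.seed``.  The returned profile holds the
    noiseless CSPs (amplitude x occupancy), i.e. exactly what
    :func:`agtitrate.equilibria.predict_csp` yields for the same model.
    """
    rng = np.random.default_rng(truth.seed)
    model = truth.build_model()
    residues = list(truth.residues)
    n_res, n_pts = len(residues), len(truth.ratios)

    free_h = rng.uniform(*H_RANGE, size=n_res)
    free_n = rng.uniform(*N_RANGE, size=n_res)
    free_int = rng.uniform(5e5, 2e6, size=n_res)

    # split each combined amplitude into 1H/15N components of random direction
    dd_h = np.zeros(n_res)
    dd_n = np.zeros(n_res)
    combined = np.zeros(n_res)
    for i, r in enumerate(residues):
        if r in truth.ddmax:
            c = truth.ddmax[r]
        elif r in truth.site_map:
            lo, hi = DDMAX_RANGE
            c = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        else:
            c = rng.uniform(*BACKGROUND_DDMAX)
        phi = rng.uniform(0.15, math.pi / 2 - 0.15)  # keep both components alive
        sign_h, sign_n = rng.choice([-1.0, 1.0], size=2)
        combined[i] = c
        dd_h[i] = sign_h * c * math.cos(phi)
        dd_n[i] = sign_n * c * math.sin(phi) / alpha

    # site occupancy per point; non-site residues follow the total-binding
    # average (light rearrangement background), which keeps them monotone
    theta = np.zeros((n_res, n_pts))
    occ_by_site: list[dict[str, float]] = []
    for j, ratio in enumerate(truth.ratios):
        st = species_state(model, truth.p_tot, ratio * truth.p_tot)
        occ_by_site.append(st.occupancies)
        mean_occ = float(np.mean(list(st.occupancies.values())))
        for i, r in enumerate(residues):
            site = truth.site_map.get(r)
            theta[i, j] = st.occupancies[site] if site else mean_occ

    points: list[TitrationPoint] = []
    truth_csp = combined[:, None] * theta
    for j, ratio in enumerate(truth.ratios):
        peaks = []
        for i, r in enumerate(residues):
            noise_h = rng.normal(0.0, truth.sigma_h) if j > 0 else 0.0
            noise_n = rng.normal(0.0, truth.sigma_n) if j > 0 else 0.0
            inten = free_int[i]
            if r in truth.intermediate and j > 0:
                site = truth.site_map.get(r)
                th = occ_by_site[j][site] if site else theta[i, j]
                inten = inten * _attenuation(th)
            peaks.append(Peak(
                assignment_label=f"{truth.res_types.get(r, 'X')}{r}N-H",
                residue_number=r,
                residue_type=truth.res_types.get(r, "X"),
                shift_h=free_h[i] + theta[i, j] * dd_h[i] + noise_h,
                shift_n=free_n[i] + theta[i, j] * dd_n[i] + noise_n,
                intensity=float(inten),
            ))
        points.append(TitrationPoint(
            ligand_total=ratio * truth.p_tot,
            receptor_totals={truth.receptor: truth.p_tot},
            molar_ratio=ratio,
            peaks=PeakList(peaks),
        ))
    series = TitrationSeries([truth.receptor], points)

    iratio = np.ones((n_res, n_pts))
    for j in range(n_pts):
        for i in range(n_res):
            iratio[i, j] = points[j].peaks.peaks[i].intensity / free_int[i]
    profile = CSPProfile(
        residues=residues,
        res_types=dict(truth.res_types),
        molar_ratios=np.asarray(truth.ratios, dtype=float),
        csp=truth_csp,
        intensity_ratio=iratio,
    )
    return series, profile


def write_truth(truth: GroundTruth, out_dir) -> Path:
    """Serialize the ground truth beside generated data (truth.json)."""
    out = Path(out_dir) / "truth.json"
    d = asdict(truth)
    d["ratios"] = list(d["ratios"])
    d["residues"] = list(d["residues"])
    d["intermediate"] = list(d["intermediate"])
    d["kds"] = list(d["kds"])
    d["res_types"] = {str(k): v for k, v in d["res_types"].items()}
    d["site_map"] = {str(k): v for k, v in d["site_map"].items()}
    d["ddmax"] = {str(k): v for k, v in d["ddmax"].items()}
    out.write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")
    return out


def simulate_to_dir(truth: GroundTruth, out_dir, dialect: str = "sparky") -> Path:
    """Generate a series and write peak lists + manifest + truth.json."""
    series, _ = generate_series(truth)
    manifest = write_series(series, out_dir, dialect=dialect)
    write_truth(truth, out_dir)
    return manifest


# ---------------------------------------------------------------------------
# presets: the published study conditions

# SilE model peptide: residues 80-90, sites K82/M83 and R89/M90, with M83 and
# M90 broadening into intermediate exchange.  Types at unnamed positions are
# synthetic filler.
_SILE_TYPES = {80: "H", 81: "A", 82: "K", 83: "M", 84: "S", 85: "Q",
               86: "E", 87: "H", 88: "A", 89: "R", 90: "M"}
_SILE_SITES = {81: SITE1, 82: SITE1, 83: SITE1, 88: SITE2, 89: SITE2, 90: SITE2}

# SilB model peptide: residues 401-430; high-affinity first-filling site
# around M416/A418/M419, weaker sequential site around R405-H408.
_SILB_TYPES = {401: "G", 402: "S", 403: "Q", 404: "A", 405: "R", 406: "M",
               407: "R", 408: "H", 409: "S", 410: "A", 411: "Q", 412: "E",
               413: "G", 414: "S", 415: "A", 416: "M", 417: "S", 418: "A",
               419: "M", 420: "Q", 421: "S", 422: "G", 423: "A", 424: "E",
               425: "S", 426: "M", 427: "Q", 428: "G", 429: "S", 430: "A"}
_SILB_SITES = {405: SITE2, 406: SITE2, 407: SITE2, 408: SITE2,
               416: SITE1, 417: SITE1, 418: SITE1, 419: SITE1}

_RATIOS_0_4 = tuple(np.round(np.linspace(0.0, 4.0, 13), 6))
_RATIOS_0_8 = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)


def _sile_p(seed: int) -> GroundTruth:
    return GroundTruth(
        name="sile_p", model_family="identical_sites", kds=(4.5e-6,),
        receptor="SilE-p", p_tot=1e-3, ratios=_RATIOS_0_4,
        residues=tuple(range(80, 91)), res_types=_SILE_TYPES,
        site_map=_SILE_SITES, intermediate=(83, 90), n_sites=2, seed=seed,
    )


def _silb_p(seed: int) -> GroundTruth:
    return GroundTruth(
        name="silb_p", model_family="sequential", kds=(4e-6, 5.71e-4),
        receptor="SilB-p", p_tot=9.2e-4, ratios=_RATIOS_0_8,
        residues=tuple(range(401, 431)), res_types=_SILB_TYPES,
        site_map=_SILB_SITES, intermediate=(), seed=seed,
    )


def _silb_p1(seed: int) -> GroundTruth:
    res = tuple(range(401, 415))
    return GroundTruth(
        name="silb_p1", model_family="one_site", kds=(8e-6,),
        receptor="SilB-p1", p_tot=1e-3, ratios=_RATIOS_0_4,
        residues=res, res_types={r: _SILB_TYPES[r] for r in res},
        site_map={r: SITE1 for r in (405, 406, 407, 408)}, seed=seed,
    )


def _silb_p2(seed: int) -> GroundTruth:
    res = tuple(range(415, 431))
    return GroundTruth(
        name="silb_p2", model_family="one_site", kds=(2e-6,),
        receptor="SilB-p2", p_tot=1e-3, ratios=_RATIOS_0_4,
        residues=res, res_types={r: _SILB_TYPES[r] for r in res},
        site_map={r: SITE1 for r in (416, 417, 418, 419)}, seed=seed,
    )


PRESETS = {
    "sile_p": _sile_p,
    "silb_p": _silb_p,
    "silb_p1": _silb_p1,
    "silb_p2": _silb_p2,
}


def preset(name: str, seed: int = 0):
    """Ground truth (or assay setup) for a named published condition.

    Single-receptor presets (``sile_p``, ``silb_p``, ``silb_p1``,
    ``silb_p2``) return a :class:`GroundTruth`.  ``mixture``,
    ``assay_fig4`` and ``assay_fig5`` return the (MixtureModel, protocol
    description) structures used by :mod:`agtitrate.competition`.
    """
    if name in PRESETS:
        return PRESETS[name](seed)
    if name in ("mixture", "assay_fig4", "assay_fig5"):
        return _competition_preset(name)
    raise KeyError(
        f"unknown preset {name!r}; valid presets: "
        f"{sorted(PRESETS) + ['mixture', 'assay_fig4', 'assay_fig5']}"
    )


def _competition_preset(name: str):
    from .competition import AssayProtocol, AssayStep

    sile = IdenticalSitesModel(kd=4.5e-6, n_sites=2)
    silb = SequentialTwoSiteModel(kd1=4e-6, kd2=5.71e-4)
    p = 0.88e-3
    if name == "mixture":
        return MixtureModel({"SilE-p": (sile, p), "SilB-p": (silb, p)})
    models = {"SilE-p": sile, "SilB-p": silb}
    if name == "assay_fig4":
        # preformed SilB/Ag 1:2, add equimolar SilE, then Ag to 1:4 and 1:8
        protocol = AssayProtocol(
            initial={"SilB-p": p, "SilE-p": 0.0},
            steps=[
                AssayStep("add_ligand", 2 * p),
                AssayStep("add_receptor", p, target="SilE-p"),
                AssayStep("add_ligand", 2 * p),
                AssayStep("add_ligand", 4 * p),
            ],
        )
    else:
        # preformed SilE/Ag 1:2, add equimolar SilB, then Ag to 1:4 and 1:8
        protocol = AssayProtocol(
            initial={"SilE-p": p, "SilB-p": 0.0},
            steps=[
                AssayStep("add_ligand", 2 * p),
                AssayStep("add_receptor", p, target="SilB-p"),
                AssayStep("add_ligand", 2 * p),
                AssayStep("add_ligand", 4 * p),
            ],
        )
    return models, protocol
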