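"""Peak-list I/O, assignment tracking, CSP computation and site mapping.

Handles assigned 2-D (1H,15N) amide peak positions from HSQC spectra of a
titration series.  Two text dialects are supported:

* ``sparky`` -- whitespace columns ``assignment  w1(15N ppm)  w2(1H ppm)
  [intensity]``, optional header line.  Note w1 is the 15N dimension and w2
  the directly detected 1H dimension.
* ``csv`` -- header ``residue,res_type,h_ppm,n_ppm,intensity``.

The combined chemical-shift perturbation of a residue between free and
bound spectra is

    CSP = sqrt(ddH^2 + (alpha * ddN)^2)

with alpha = 0.14 by default (the community weighting for the narrower 15N
dispersion; 0.20 is sometimes used for glycine).  Residues whose peaks
broaden away during the titration report intermediate-to-slow exchange and
are flagged rather than fitted.
"""

from __future__ import annotations

import csv as _csv
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "TitrationPoint",
    "TitrationSeries",
    "CSPProfile",
    "DEFAULT_ALPHA",
    "read_peak_list",
    "write_peak_list",
    "compute_csp",
    "track_assignments",
    "build_profile",
    "classify_exchange",
    "map_binding_sites",
    "load_series",
    "write_series",
]

DEFAULT_ALPHA = 0.14

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)(?:N-H|NH|N-HN|H?N)?$")


class PeakListError(ValueError):
    """Malformed or inconsistent peak-list input."""


@dataclass(frozen=True)
class Peak:
    """One assigned backbone-amide cross peak."""

    assignment_label: str
    residue_number: int
    residue_type: str
    shift_h: float
    shift_n: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift_h <= 16.0:
            raise PeakListError(
                f"{self.assignment_label}: 1H shift {self.shift_h} outside [0, 16] ppm"
            )
        if not 90.0 <= self.shift_n <= 140.0:
            warnings.warn(
                f"{self.assignment_label}: 15N shift {self.shift_n} outside the "
                "typical backbone-amide range [90, 140] ppm",
                stacklevel=2,
            )

    def distance(self, other: "Peak", alpha: float = DEFAULT_ALPHA) -> float:
        """Weighted ppm distance sqrt(dH^2 + (alpha*dN)^2) to another peak."""
        dh = self.shift_h - other.shift_h
        dn = self.shift_n - other.shift_n
        return math.hypot(dh, alpha * dn)


@dataclass
class PeakList:
    """Ordered collection of peaks with unique residue numbers."""

    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.peaks:
            if p.residue_number in seen:
                raise PeakListError(f"duplicate assignment for residue {p.residue_number}")
            seen.add(p.residue_number)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def by_residue(self) -> dict[int, Peak]:
        return {p.residue_number: p for p in self.peaks}


def _parse_label(label: str) -> tuple[str, int]:
    m = _LABEL_RE.match(label)
    if m is None:
        raise PeakListError(f"cannot parse assignment label {label!r}")
    return m.group(1).upper(), int(m.group(2))


def read_peak_list(path, dialect: str = "sparky") -> PeakList:
    """Read a peak list in the ``sparky`` or ``csv`` dialect."""
    path = Path(path)
    if dialect == "sparky":
        return _read_sparky(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'sparky' or 'csv')")


def _read_sparky(path: Path) -> PeakList:
    peaks: list[Peak] = []
    lines = path.read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.lower().startswith("assignment"):
            continue  # header
        cols = line.split()
        if len(cols) not in (3, 4):
            raise PeakListError(f"{path}:{lineno}: expected 3-4 columns, got {len(cols)}")
        try:
            res_type, res_num = _parse_label(cols[0])
            shift_n = float(cols[1])
            shift_h = float(cols[2])
            intensity = float(cols[3]) if len(cols) == 4 else None
        except (ValueError, PeakListError) as exc:
            raise PeakListError(f"{path}:{lineno}: {exc}") from exc
        peaks.append(
            Peak(cols[0], res_num, res_type, shift_h=shift_h, shift_n=shift_n,
                 intensity=intensity)
        )
    if not peaks:
        warnings.warn(f"{path}: empty peak list", stacklevel=2)
    return PeakList(peaks)


def _read_csv(path: Path) -> PeakList:
    peaks: list[Peak] = []
    with path.open(newline="") as fh:
        reader = _csv.DictReader(fh)
        expected = {"residue", "res_type", "h_ppm", "n_ppm", "intensity"}
        if reader.fieldnames is None or not expected <= set(reader.fieldnames):
            raise PeakListError(
                f"{path}: csv dialect needs header {','.join(sorted(expected))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                res_num = int(row["residue"])
                res_type = row["res_type"].strip().upper()
                shift_h = float(row["h_ppm"])
                shift_n = float(row["n_ppm"])
                raw_i = (row["intensity"] or "").strip()
                intensity = float(raw_i) if raw_i else None
            except (TypeError, ValueError) as exc:
                raise PeakListError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(
                Peak(f"{res_type}{res_num}N-H", res_num, res_type,
                     shift_h=shift_h, shift_n=shift_n, intensity=intensity)
            )
    if not peaks:
        warnings.warn(f"{path}: empty peak list", stacklevel=2)
    return PeakList(peaks)


def write_peak_list(peaklist: PeakList, path, dialect: str = "sparky") -> None:
    """Write a peak list; round-trips losslessly through :func:`read_peak_list`."""
    path = Path(path)
    if dialect == "sparky":
        lines = ["      Assignment         w1         w2   Data Height"]
        for p in peaklist:
            cols = f"{p.assignment_label:>16s} {p.shift_n:10.4f} {p.shift_h:10.4f}"
            if p.intensity is not None:
                cols += f" {p.intensity:14.6e}"
            lines.append(cols)
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "csv":
        with path.open("w", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["residue", "res_type", "h_ppm", "n_ppm", "intensity"])
            for p in peaklist:
                writer.writerow([
                    p.residue_number, p.residue_type,
                    repr(p.shift_h), repr(p.shift_n),
                    "" if p.intensity is None else repr(p.intensity),
                ])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: total concentrations plus the observed peaks."""

    ligand_total: float
    receptor_totals: dict[str, float]
    molar_ratio: float
    peaks: PeakList

    def __post_init__(self) -> None:
        if self.ligand_total < 0 or any(v < 0 for v in self.receptor_totals.values()):
            raise ValueError("concentrations must be >= 0")
        ref = next(iter(self.receptor_totals.values()))
        if ref > 0:
            implied = self.ligand_total / ref
            if abs(implied - self.molar_ratio) > 1e-9 * max(1.0, abs(implied)):
                raise ValueError(
                    f"molar_ratio {self.molar_ratio} inconsistent with "
                    f"L_tot/P_tot = {implied}"
                )


@dataclass
class TitrationSeries:
    """Ordered titration points; the first point is the ligand-free state."""

    receptor_names: list[str]
    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("series needs at least one point")
        if self.points[0].ligand_total != 0.0:
            raise ValueError("first point must be the free state (ligand_total = 0)")
        l_tots = [p.ligand_total for p in self.points]
        if any(b < a for a, b in zip(l_tots, l_tots[1:])):
            raise ValueError("ligand_total must be non-decreasing across points")
        free = set(self.points[0].peaks.by_residue())
        for i, pt in enumerate(self.points[1:], start=1):
            extra = {p.residue_number for p in pt.peaks} - free
            if extra:
                raise ValueError(
                    f"point {i}: peaks for residues {sorted(extra)} absent from the "
                    "free state (peaks may disappear, never appear)"
                )

    @property
    def free_point(self) -> TitrationPoint:
        return self.points[0]

    @property
    def molar_ratios(self) -> np.ndarray:
        return np.array([p.molar_ratio for p in self.points])


def compute_csp(free: Peak, bound: Peak, alpha: float = DEFAULT_ALPHA) -> float:
    """Combined CSP sqrt(ddH^2 + (alpha*ddN)^2) between matched peaks."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if free.residue_number != bound.residue_number:
        raise PeakListError(
            f"assignment mismatch: {free.assignment_label} vs {bound.assignment_label}"
        )
    return free.distance(bound, alpha=alpha)


def track_assignments(
    series: TitrationSeries,
    max_dist: float = 0.05,
    alpha: float = DEFAULT_ALPHA,
) -> TitrationSeries:
    """Propagate free-state assignments through the series point by point.

    Each point's peaks are matched to the previous point's assigned peaks by
    the minimal-total-weighted-distance assignment (Hungarian algorithm, so
    crossing trajectories resolve globally); matches farther than
    ``max_dist`` ppm-equivalents are dropped, and ties break toward the
    lower residue number by construction.  Tracking chains point-to-point
    because cumulative shifts at high molar ratio exceed the spacing
    between neighbouring peaks.
    """
    from scipy.optimize import linear_sum_assignment

    big = 1e6  # sentinel cost for forbidden (> max_dist) pairings
    new_points = [series.points[0]]
    prev = {p.residue_number: p for p in series.points[0].peaks}
    for pt in series.points[1:]:
        prev_res = sorted(prev)  # sorted -> deterministic tie resolution
        cost = np.full((len(pt.peaks), len(prev_res)), big)
        for j, peak in enumerate(pt.peaks):
            for k, res in enumerate(prev_res):
                d = peak.distance(prev[res], alpha=alpha)
                if d <= max_dist:
                    cost[j, k] = d
        matched: dict[int, int] = {}
        if cost.size:
            rows, cols = linear_sum_assignment(cost)
            for j, k in zip(rows, cols):
                if cost[j, k] < big:
                    matched[j] = prev_res[k]
        new_peaks = []
        for j, peak in enumerate(pt.peaks):
            if j in matched:
                res = matched[j]
                ref = prev[res]
                new_peaks.append(replace(
                    peak,
                    assignment_label=ref.assignment_label,
                    residue_number=res,
                    residue_type=ref.residue_type,
                ))
        new_pt = TitrationPoint(
            ligand_total=pt.ligand_total,
            receptor_totals=pt.receptor_totals,
            molar_ratio=pt.molar_ratio,
            peaks=PeakList(new_peaks),
        )
        new_points.append(new_pt)
        prev = {p.residue_number: p for p in new_peaks}
    return TitrationSeries(series.receptor_names, new_points)


FLAG_FAST = "fast"
FLAG_INTERMEDIATE = "intermediate"
FLAG_LOST = "lost"


@dataclass
class CSPProfile:
    """Per-residue CSP and intensity trajectories across a titration.

    ``csp[i, j]`` is the combined CSP (ppm) of residue ``residues[i]`` at
    point j (0 at the free state); ``intensity_ratio`` is I_point/I_free
    (NaN where intensities are unknown or the peak is lost).
    """

    residues: list[int]
    res_types: dict[int, str]
    molar_ratios: np.ndarray
    csp: np.ndarray
    intensity_ratio: np.ndarray
    exchange_flag: dict[int, str] = field(default_factory=dict)
    significant: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.csp = np.asarray(self.csp, dtype=float)
        if np.any(self.csp[~np.isnan(self.csp)] < 0):
            raise ValueError("CSPs must be >= 0")
        if np.any(self.csp[:, 0][~np.isnan(self.csp[:, 0])] != 0):
            raise ValueError("CSP must be 0 at the free-state point")

    def index(self, residue: int) -> int:
        return self.residues.index(residue)

    def final_csp(self, residue: int) -> float:
        row = self.csp[self.index(residue)]
        finite = row[~np.isnan(row)]
        return float(finite[-1]) if finite.size else math.nan

    def to_frame(self) -> pd.DataFrame:
        """Long-format table matching the exported CSV schema."""
        rows = []
        for i, res in enumerate(self.residues):
            for j, ratio in enumerate(self.molar_ratios):
                rows.append({
                    "residue": res,
                    "res_type": self.res_types.get(res, "X"),
                    "point_index": j,
                    "molar_ratio": ratio,
                    "csp_ppm": self.csp[i, j],
                    "intensity_ratio": self.intensity_ratio[i, j],
                    "exchange_flag": self.exchange_flag.get(res, FLAG_FAST),
                    "significant": self.significant.get(res, False),
                })
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CSPProfile":
        """Rebuild a profile from the long-format CSV written by write_csv."""
        df = pd.read_csv(path)
        residues = sorted(df["residue"].unique())
        pts = sorted(df["point_index"].unique())
        csp = np.full((len(residues), len(pts)), np.nan)
        iratio = np.full((len(residues), len(pts)), np.nan)
        ratios = np.zeros(len(pts))
        res_types: dict[int, str] = {}
        flags: dict[int, str] = {}
        sig: dict[int, bool] = {}
        idx = {r: i for i, r in enumerate(residues)}
        for row in df.itertuples():
            i, j = idx[row.residue], int(row.point_index)
            csp[i, j] = row.csp_ppm
            iratio[i, j] = row.intensity_ratio
            ratios[j] = row.molar_ratio
            res_types[row.residue] = str(row.res_type)
            flags[row.residue] = str(row.exchange_flag)
            sig[row.residue] = bool(row.significant)
        return cls(
            residues=list(residues), res_types=res_types, molar_ratios=ratios,
            csp=csp, intensity_ratio=iratio, exchange_flag=flags, significant=sig,
        )


def build_profile(series: TitrationSeries, alpha: float = DEFAULT_ALPHA) -> CSPProfile:
    """Compute per-residue CSP and intensity-ratio trajectories.

    A residue whose peak is missing from some point gets NaN CSP/intensity
    there (and is later flagged ``lost`` by :func:`classify_exchange`).
    """
    free = series.free_point.peaks.by_residue()
    residues = sorted(free)
    n_pts = len(series.points)
    csp = np.zeros((len(residues), n_pts))
    iratio = np.full((len(residues), n_pts), np.nan)
    for i, res in enumerate(residues):
        f = free[res]
        if f.intensity:
            iratio[i, 0] = 1.0
        for j, pt in enumerate(series.points[1:], start=1):
            peak = pt.peaks.by_residue().get(res)
            if peak is None:
                csp[i, j] = np.nan
                continue
            csp[i, j] = compute_csp(f, peak, alpha=alpha)
            if f.intensity and peak.intensity is not None:
                iratio[i, j] = peak.intensity / f.intensity
    return CSPProfile(
        residues=residues,
        res_types={r: free[r].residue_type for r in residues},
        molar_ratios=series.molar_ratios,
        csp=csp,
        intensity_ratio=iratio,
    )


def classify_exchange(profile: CSPProfile, intensity_threshold: float = 0.3) -> CSPProfile:
    """Flag each residue fast / intermediate / lost from its intensity trace.

    ``intermediate``: the peak stays observable but its intensity drops below
    ``intensity_threshold`` of the free-state value at some point (exchange
    broadening); ``lost``: the peak disappears entirely; ``fast`` otherwise.
    """
    if not 0.0 < intensity_threshold < 1.0:
        raise ValueError("intensity_threshold must be in (0, 1)")
    have_any = np.any(np.isfinite(profile.intensity_ratio[:, 1:]))
    for i, res in enumerate(profile.residues):
        if np.any(np.isnan(profile.csp[i])):
            profile.exchange_flag[res] = FLAG_LOST
            continue
        if not have_any:
            profile.exchange_flag[res] = FLAG_FAST
            continue
        ratios = profile.intensity_ratio[i]
        finite = ratios[np.isfinite(ratios)]
        if finite.size and np.min(finite) < intensity_threshold:
            profile.exchange_flag[res] = FLAG_INTERMEDIATE
        else:
            profile.exchange_flag[res] = FLAG_FAST
    if not have_any:
        warnings.warn("no intensity data: all residues flagged 'fast'", stacklevel=2)
    return profile


def map_binding_sites(profile: CSPProfile, k_sigma: float = 1.0) -> list[list[int]]:
    """Significant-CSP clustering into candidate binding sites.

    The significance cutoff is mean + k_sigma*SD of the final-point CSPs of
    fast-exchange residues, recomputed once after trimming residues above
    the first-pass cutoff.  Residues above the cutoff, or flagged
    intermediate/lost, are significant; clusters are maximal runs of
    significant residues tolerating single-residue gaps.
    """
    if k_sigma < 0:
        raise ValueError("k_sigma must be >= 0")
    if len(profile.residues) < 4:
        raise ValueError("need at least 4 residues to define a significance threshold")
    flags = profile.exchange_flag
    fast = [r for r in profile.residues if flags.get(r, FLAG_FAST) == FLAG_FAST]
    finals = np.array([profile.final_csp(r) for r in fast])
    thresh = finals.mean() + k_sigma * finals.std(ddof=0)
    keep = finals <= thresh
    if keep.any() and not keep.all():
        trimmed = finals[keep]
        thresh = trimmed.mean() + k_sigma * trimmed.std(ddof=0)
    for r in profile.residues:
        flag = flags.get(r, FLAG_FAST)
        if flag in (FLAG_INTERMEDIATE, FLAG_LOST):
            profile.significant[r] = True
        else:
            profile.significant[r] = bool(profile.final_csp(r) > thresh)
    sig = sorted(r for r, s in profile.significant.items() if s)
    clusters: list[list[int]] = []
    for r in sig:
        if clusters and r - clusters[-1][-1] <= 2:  # allow one-residue gaps
            clusters[-1].append(r)
        else:
            clusters.append([r])
    return clusters


def load_series(manifest_path) -> TitrationSeries:
    """Load a titration series from a TOML manifest.

    Schema::

        receptors = ["SilE-p"]
        dialect = "sparky"              # optional, default sparky
        [[point]]
        file = "point_00.list"          # relative to the manifest
        ligand_total = 0.0
        [point.receptor_totals]
        "SilE-p" = 1e-3
    """
    import tomllib

    manifest_path = Path(manifest_path)
    with manifest_path.open("rb") as fh:
        cfg = tomllib.load(fh)
    dialect = cfg.get("dialect", "sparky")
    receptors = list(cfg["receptors"])
    points = []
    for entry in cfg["point"]:
        peaks = read_peak_list(manifest_path.parent / entry["file"], dialect=dialect)
        rt = {k: float(v) for k, v in entry["receptor_totals"].items()}
        l_tot = float(entry["ligand_total"])
        ref = rt[receptors[0]]
        points.append(TitrationPoint(
            ligand_total=l_tot,
            receptor_totals=rt,
            molar_ratio=entry.get("molar_ratio", l_tot / ref if ref else 0.0),
            peaks=peaks,
        ))
    return TitrationSeries(receptors, points)


def write_series(series: TitrationSeries, out_dir, dialect: str = "sparky") -> Path:
    """Write per-point peak lists plus a TOML manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "list" if dialect == "sparky" else "csv"
    lines = [
        "receptors = [" + ", ".join(f'"{n}"' for n in series.receptor_names) + "]",
        f'dialect = "{dialect}"',
    ]
    for j, pt in enumerate(series.points):
        fname = f"point_{j:02d}.{ext}"
        write_peak_list(pt.peaks, out_dir / fname, dialect=dialect)
        lines += [
            "",
            "[[point]]",
            f'file = "{fname}"',
            f"ligand_total = {float(pt.ligand_total)!r}",
            f"molar_ratio = {float(pt.molar_ratio)!r}",
            "[point.receptor_totals]",
        ]
        lines += [f'"{k}" = {float(v)!r}' for k, v in pt.receptor_totals.items()]
    manifest = out_dir / "series.toml"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
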