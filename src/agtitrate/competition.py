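"""Stepwise competition assays between silver-binding receptors.

Replays ligand/receptor addition protocols purely thermodynamically: after
every addition the full mixture equilibrium is re-solved, so the trajectory
is path-independent (only cumulative totals matter).  The observable of
interest is how adding a competitor receptor pulls ligand off an existing
receptor's sites ("shift back" of its peaks toward the free positions),
and how far further ligand additions restore the original occupancies.

Concentrations are given on a post-mixing basis (dilution bookkeeping is
the caller's concern), matching how titration ratios are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .equilibria import MixtureModel, SpeciesState, species_state

__all__ = [
    "AssayStep",
    "AssayProtocol",
    "AssayTrajectory",
    "run_protocol",
    "displacement_metrics",
]

ACTIONS = ("add_ligand", "add_receptor")


@dataclass(frozen=True)
class AssayStep:
    """One addition: ``amount`` is a concentration increment (mol/L)."""

    action: str
    amount: float
    target: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"action must be one of {ACTIONS}, got {self.action!r}")
        if not self.amount > 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if self.action == "add_receptor" and not self.target:
            raise ValueError("add_receptor needs a target receptor name")


@dataclass
class AssayProtocol:
    """Initial receptor concentrations plus an ordered list of additions."""

    initial: dict[str, float]
    steps: list[AssayStep]
    l_tot_initial: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.initial.values()) or self.l_tot_initial < 0:
            raise ValueError("initial concentrations must be >= 0")


@dataclass
class StepRecord:
    """Equilibrium after one protocol step."""

    step_index: int
    action: str
    l_tot: float
    receptor_totals: dict[str, float]
    state: SpeciesState
    csp: dict = field(default_factory=dict)


@dataclass
class AssayTrajectory:
    """Sequence of equilibria along a protocol (index 0 = initial state)."""

    records: list[StepRecord]

    def occupancy(self, site: str) -> list[float]:
        return [rec.state.occupancies[site] for rec in self.records]


def run_protocol(
    protocol: AssayProtocol,
    models: dict[str, object],
    amplitudes: dict | None = None,
) -> AssayTrajectory:
    """Replay a protocol, re-solving the mixture equilibrium after each step.

    ``models`` maps receptor name -> binding model; ``amplitudes`` (optional)
    maps residue -> (ddmax_ppm, "receptor:site") to also predict per-residue
    CSPs relative to each receptor's free state.
    """
    missing = set(protocol.initial) - set(models)
    for s in protocol.steps:
        if s.action == "add_receptor" and s.target not in models:
            missing.add(s.target)
    if missing:
        raise KeyError(f"no model for receptors {sorted(missing)}")

    totals = dict(protocol.initial)
    for name in models:
        totals.setdefault(name, 0.0)
    l_tot = protocol.l_tot_initial
    records: list[StepRecord] = []

    def snapshot(idx: int, action: str) -> StepRecord:
        mix = MixtureModel({n: (models[n], totals[n]) for n in models})
        state = species_state(mix, None, l_tot)
        rec = StepRecord(
            step_index=idx, action=action, l_tot=l_tot,
            receptor_totals=dict(totals), state=state,
        )
        if amplitudes:
            rec.csp = {
                res: dd * state.occupancies[site]
                for res, (dd, site) in amplitudes.items()
            }
        return rec

    records.append(snapshot(0, "initial"))
    for i, step in enumerate(protocol.steps, start=1):
        if step.action == "add_ligand":
            l_tot += step.amount
        else:
            totals[step.target] = totals.get(step.target, 0.0) + step.amount
        records.append(snapshot(i, step.action))
    return AssayTrajectory(records)


def displacement_metrics(traj: AssayTrajectory) -> dict[str, dict[str, float | None]]:
    """Per-site displacement summary around the competitor-addition step.

    For each site, with theta_before the occupancy just before the (last)
    ``add_receptor`` step, theta_after just after it, and theta_final at the
    end of the protocol:

    * ``shiftback_fraction`` = (theta_before - theta_after) / theta_before --
      how far the competitor stripped the site (the "shift back" of its
      peaks toward free positions);
    * ``recovery_ratio`` = theta_final / theta_before -- how far subsequent
      ligand additions restored it.

    Sites starting unoccupied report None for both.
    """
    add_idx = [r.step_index for r in traj.records if r.action == "add_receptor"]
    if not add_idx:
        raise ValueError("protocol has no add_receptor step")
    idx = add_idx[-1]
    after_actions = [r.action for r in traj.records if r.step_index > idx]
    if "add_ligand" not in after_actions:
        raise ValueError("need at least one add_ligand step after the competitor")
    before = traj.records[idx - 1].state.occupancies
    after = traj.records[idx].state.occupancies
    final = traj.records[-1].state.occupancies
    out: dict[str, dict[str, float | None]] = {}
    for site, theta_b in before.items():
        if theta_b == 0.0:
            out[site] = {"shiftback_fraction": None, "recovery_ratio": None}
        else:
            out[site] = {
                "shiftback_fraction": (theta_b - after[site]) / theta_b,
                "recovery_ratio": final[site] / theta_b,
            }
    return out
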