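"""End-to-end mutation analysis: ensemble decomposition, annotated
per-residue profiles, and the three-factor design ranking.

``profile`` runs the charging decomposition over wild-type and mutant frame
ensembles, differences the per-residue ensemble means through the residue
correspondence, and annotates each residue with the local-environment
quantities (d_m, charge class, census membership, salt-bridge changes).
``rank_candidates`` codifies the three design factors — total net charge,
mutation content, and local net charge within ~15 A — into a transparent
heuristic score for candidate ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .local_environment import (
    bulky_flag,
    charge_census,
    min_sidechain_distance,
    relative_exposure,
    salt_bridge_delta,
)
from .mutation_model import MutationSet, build_correspondence
from .solvation_core import (
    ChargingPath,
    LowDensityProvider,
    SolventModel,
    ThermodynamicState,
    charging_decomposition,
    delta_g_solv,
    group_by_residue,
    solute_sites_from_structure,
    water_model,
    DeltaGStats,
)
from .structure_io import ChargedStructure, ResidueKey, rmsd_trace

__all__ = [
    "ProfileConfig",
    "ProfileRow",
    "ProfileResult",
    "CandidateScore",
    "DesignReport",
    "profile",
    "rank_candidates",
    "write_outputs",
]


@dataclass
class ProfileConfig:
    """Numerical settings of the analysis pipeline.

    The defaults are desk-scale: a 15 A census cutoff, the 4 A / 50%
    salt-bridge criterion, an 8+8-node two-stage charging path, and modest
    grid resolutions for either backend.
    """

    cutoff: float = 15.0  # census cutoff, A
    sb_distance: float = 4.0
    sb_occupancy: float = 0.5
    rmsd_threshold: float = 3.0
    temperature: float = 300.0
    n_lj_nodes: int = 8
    n_coulomb_nodes: int = 8
    # low-density backend support
    ld_spacing: float = 0.3
    ld_padding: float = 8.0
    ld_r_max: float = 25.0
    ld_dr: float = 0.02
    # 3D-RISM backend
    grid_spacing: float = 0.5
    grid_padding: float = 8.0
    rism_tol: float = 1e-5
    mdiis_depth: int = 10
    damping: float = 0.3

    @property
    def state(self) -> ThermodynamicState:
        return ThermodynamicState(self.temperature)

    @property
    def path(self) -> ChargingPath:
        return ChargingPath.two_stage(self.n_lj_nodes, self.n_coulomb_nodes)


@dataclass
class ProfileRow:
    key: str  # wild-type residue key (mutant key for inserted residues)
    aa_wt: str
    aa_mut: str
    charge_class: str
    d_m: float
    in_census: bool
    is_site: bool
    sb_formed: bool
    sb_broken: bool
    sb_involves_site: bool
    status: str  # matched | inserted | deleted
    delta_g: float  # kcal/mol; deleted residues enter with their negative


@dataclass
class ProfileResult:
    rows: list
    stats: "DeltaGStats"
    wt_total_mean: float
    mut_total_mean: float
    metadata: dict = field(default_factory=dict)

    @property
    def residue_sum(self) -> float:
        return float(sum(r.delta_g for r in self.rows))

    def to_frame(self) -> pd.DataFrame:
        cols = ["key", "aa_wt", "aa_mut", "charge_class", "d_m",
                "in_census", "is_site", "sb_formed", "sb_broken",
                "sb_involves_site", "status", "delta_g"]
        return pd.DataFrame([asdict(r) for r in self.rows], columns=cols)


def _decompose_frame(cs: ChargedStructure, frame: np.ndarray,
                     solvent: SolventModel, backend: str,
                     cfg: ProfileConfig, susceptibility=None):
    solute = solute_sites_from_structure(cs, frame=frame)
    if backend == "lowdensity":
        provider = LowDensityProvider(
            solute, solvent, cfg.state, r_max=cfg.ld_r_max, dr=cfg.ld_dr,
            spacing=cfg.ld_spacing, padding=cfg.ld_padding)
    elif backend == "rism":
        from .rism_backend import Grid3D, RismProvider, analytic_susceptibility

        sus = susceptibility or analytic_susceptibility(solvent)
        grid = Grid3D.around_solute(solute, spacing=cfg.grid_spacing,
                                    padding=cfg.grid_padding)
        provider = RismProvider(
            solute, sus, grid, cfg.state, tol=cfg.rism_tol,
            mdiis_depth=cfg.mdiis_depth, damping=cfg.damping)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    dr = charging_decomposition(solute, solvent, provider, cfg.path,
                                cfg.state)
    return dr.total, group_by_residue(dr, cs)


def _ensemble_means(runs, solvent, backend, cfg, susceptibility=None):
    """Per-run total traces and the ensemble per-residue mean."""
    totals_per_run = []
    res_sums: dict = {}
    n_frames = 0
    for run_idx, ens in enumerate(runs):
        totals = []
        for f_idx, frame in enumerate(ens.frames):
            try:
                total, per_res = _decompose_frame(
                    ens, frame, solvent, backend, cfg, susceptibility)
            except Exception as exc:
                raise RuntimeError(
                    f"backend failed at run {run_idx} frame {f_idx}: {exc}"
                ) from exc
            totals.append(total)
            for key, val in per_res.items():
                res_sums[key] = res_sums.get(key, 0.0) + val
            n_frames += 1
        totals_per_run.append(np.array(totals))
    res_means = {k: v / n_frames for k, v in res_sums.items()}
    return totals_per_run, res_means


def profile(
    wt_runs,
    mut_runs,
    ms: MutationSet,
    solvent: SolventModel | None = None,
    backend: str = "lowdensity",
    config: ProfileConfig | None = None,
    susceptibility=None,
) -> ProfileResult:
    """Residue-wise dG_solv profile of a mutation.

    ``wt_runs``/``mut_runs`` are lists of charged frame ensembles (one per
    independent run; a bare ensemble is accepted as a single run).  Per-frame
    decompositions are averaged per residue within each ensemble, and the
    mutant-minus-wild-type difference is taken through the residue
    correspondence.  Local annotations are computed on the first wild-type
    frame.  Ensembles that exceed the RMSD stability threshold trigger a
    warning, not a failure.
    """
    cfg = config or ProfileConfig()
    solvent = solvent or water_model()
    if isinstance(wt_runs, ChargedStructure):
        wt_runs = [wt_runs]
    if isinstance(mut_runs, ChargedStructure):
        mut_runs = [mut_runs]

    for label, runs in (("wild-type", wt_runs), ("mutant", mut_runs)):
        for ens in runs:
            trace = rmsd_trace(ens, threshold=cfg.rmsd_threshold)
            if not trace.passes_gate:
                warnings.warn(
                    f"{label} run {ens.run_id}: max C-alpha RMSD "
                    f"{trace.max:.2f} A exceeds the {cfg.rmsd_threshold} A "
                    "stability threshold", stacklevel=2)

    wt0, mut0 = wt_runs[0], mut_runs[0]
    cmap = build_correspondence(wt0, mut0, ms)
    sites = ms.site_keys()

    wt_totals, wt_means = _ensemble_means(wt_runs, solvent, backend, cfg,
                                          susceptibility)
    mut_totals, mut_means = _ensemble_means(mut_runs, solvent, backend, cfg,
                                            susceptibility)
    stats = delta_g_solv(wt_totals, mut_totals)

    # annotations on the wild-type first frame
    d_m = {r.key: (min_sidechain_distance(wt0, r.key, sites)
                   if sites else np.inf)
           for r in wt0.residues}
    formed, broken, involves = salt_bridge_delta(
        _pool_runs(wt_runs), _pool_runs(mut_runs), cmap, site_keys=sites,
        occupancy_threshold=cfg.sb_occupancy,
        distance_cutoff=cfg.sb_distance)
    formed_res = {k for b in formed for k in b.pair}
    broken_res = {k for b in broken for k in b.pair}
    involved_res = {k for b in formed + broken for k in b.pair
                    if involves.get(b.pair)}

    def _class(res) -> str:
        q = res.formal_charge
        return "positive" if q > 0 else "negative" if q < 0 else "neutral"

    rows: list[ProfileRow] = []
    mut_res_map = {r.key: r for r in mut0.residues}
    for r in wt0.residues:
        key = r.key
        mkey = cmap.pairs.get(key)
        if mkey is not None:
            dg = mut_means.get(mkey, 0.0) - wt_means.get(key, 0.0)
            status = "matched"
            aa_mut = mut_res_map[mkey].one_letter
        else:
            dg = -wt_means.get(key, 0.0)
            status = "deleted"
            aa_mut = "-"
        rows.append(ProfileRow(
            key=str(key), aa_wt=r.one_letter, aa_mut=aa_mut,
            charge_class=_class(r), d_m=float(d_m[key]),
            in_census=bool(0.0 < d_m[key] <= cfg.cutoff),
            is_site=key in sites,
            sb_formed=key in formed_res, sb_broken=key in broken_res,
            sb_involves_site=key in involved_res,
            status=status, delta_g=float(dg),
        ))
    for key in cmap.mutant_only:
        r = mut_res_map[key]
        rows.append(ProfileRow(
            key=str(key), aa_wt="-", aa_mut=r.one_letter,
            charge_class=_class(r), d_m=0.0, in_census=False, is_site=True,
            sb_formed=key in formed_res, sb_broken=False,
            sb_involves_site=key in involved_res,
            status="inserted", delta_g=float(mut_means.get(key, 0.0)),
        ))

    census = (charge_census(wt0, sites, cutoff=cfg.cutoff)
              if sites else None)
    result = ProfileResult(
        rows=rows, stats=stats,
        wt_total_mean=float(np.mean(np.concatenate(wt_totals))),
        mut_total_mean=float(np.mean(np.concatenate(mut_totals))),
        metadata={
            "backend": backend,
            "mutations": [str(m) for m in ms],
            "delta_q": ms.delta_q,
            "census": None if census is None else {
                "cutoff": census.cutoff,
                "n_positive": census.n_positive,
                "n_negative": census.n_negative,
                "local_net": census.local_net,
            },
            "wt_net_charge": wt0.total_charge,
            "mut_net_charge": mut0.total_charge,
            "n_runs": len(wt_runs),
            "n_frames": [int(e.n_frames) for e in wt_runs],
            "config": asdict(cfg),
            "path": cfg.path.describe(),
        },
    )
    return result


def _pool_runs(runs) -> ChargedStructure:
    """Concatenate the frames of several runs into one ensemble (for
    occupancy statistics)."""
    pooled = runs[0].with_frames(
        [f for ens in runs for f in ens.frames])
    return pooled


# ---------------------------------------------------------------------------
# Design ranking
# ---------------------------------------------------------------------------

@dataclass
class CandidateScore:
    site: str
    wt_aa: str
    mut_aa: str
    delta_q: int
    q_total: int
    local_net: int
    bulky: bool
    rel_sasa: float
    score: float
    rank: int = 0


@dataclass
class DesignReport:
    candidates: list  # ranked CandidateScore rows
    excluded: list  # (site, mut_aa, reason)
    weights: dict
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = ["rank", "site", "wt_aa", "mut_aa", "delta_q", "q_total",
                "local_net", "bulky", "rel_sasa", "score"]
        return pd.DataFrame([asdict(c) for c in self.candidates],
                            columns=cols)


def rank_candidates(
    cs: ChargedStructure,
    candidate_sites,
    mutation_types,
    cutoff: float = 15.0,
    weights: dict | None = None,
    exposure_threshold: float = 0.25,
) -> DesignReport:
    """Rank candidate charged mutations by the three-factor heuristic.

    score = -(w_g * Q_total * dQ + w_l * local_net * dQ) + w_b * bulky;
    lower is predicted more favourable (more negative dG_solv).  Sites whose
    relative exposure falls below ``exposure_threshold`` are excluded with a
    recorded reason; all three factor values are reported so users can
    re-weight.  Ties break deterministically by (score, chain, position).
    """
    from .constants import aa_charge

    w = {"global": 1.0, "local": 1.0, "bulky": 100.0}
    if weights:
        w.update(weights)
    q_total = cs.total_charge
    exposure = relative_exposure(cs)

    rows, excluded = [], []
    for site in candidate_sites:
        idx = cs.residue_by_key(site)
        wt_res = cs.residues[idx]
        rel = exposure.get(site, 0.0)
        if rel < exposure_threshold:
            for mut_aa in mutation_types:
                excluded.append((str(site), mut_aa,
                                 f"site not solvent-exposed "
                                 f"(relative SASA {rel:.2f} < "
                                 f"{exposure_threshold})"))
            continue
        local_net = charge_census(cs, site, cutoff=cutoff).local_net
        for mut_aa in mutation_types:
            dq = aa_charge(mut_aa) - wt_res.formal_charge
            bulky = bulky_flag(mut_aa)
            score = (-(w["global"] * q_total * dq
                       + w["local"] * local_net * dq)
                     + w["bulky"] * bulky)
            rows.append(CandidateScore(
                site=str(site), wt_aa=wt_res.one_letter, mut_aa=mut_aa,
                delta_q=int(dq), q_total=int(q_total),
                local_net=int(local_net), bulky=bool(bulky),
                rel_sasa=float(rel), score=float(score),
            ))
    rows.sort(key=lambda c: (c.score, c.site, c.mut_aa))
    for i, c in enumerate(rows):
        c.rank = i + 1
    return DesignReport(
        candidates=rows, excluded=excluded, weights=w,
        metadata={"cutoff": cutoff,
                  "exposure_threshold": exposure_threshold},
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_outputs(result, prefix: str) -> dict:
    """Write a profile or design report as CSV (per-residue/candidate rows)
    + JSON (totals, errors, config echo); returns the paths written.
    Outputs are deterministic: fixed column order and sorted JSON keys."""
    paths = {}
    if isinstance(result, ProfileResult):
        csv_path, json_path = f"{prefix}_profile.csv", f"{prefix}_profile.json"
        result.to_frame().to_csv(csv_path, index=False)
        payload = {
            "delta_g_mean": result.stats.mean,
            "delta_g_se": result.stats.se,
            "per_run_delta": result.stats.per_run_delta,
            "per_run_sd": result.stats.per_run_sd,
            "wt_total_mean": result.wt_total_mean,
            "mut_total_mean": result.mut_total_mean,
            "residue_sum": result.residue_sum,
            "metadata": result.metadata,
        }
    elif isinstance(result, DesignReport):
        csv_path, json_path = f"{prefix}_rank.csv", f"{prefix}_rank.json"
        result.to_frame().to_csv(csv_path, index=False)
        payload = {
            "excluded": [list(e) for e in result.excluded],
            "weights": result.weights,
            "metadata": result.metadata,
        }
    else:
        raise TypeError(f"cannot write {type(result).__name__}")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["csv"] = csv_path
    paths["json"] = json_path
    return paths


def read_profile_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
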