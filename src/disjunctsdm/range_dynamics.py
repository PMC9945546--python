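"""Aggregate models, consensus ensembles, range change, and orchestration.

The aggregate model treats a cell as suitable when the core model, the
disjunct model, or both predict it suitable (cellwise union) -- a distribution
hypothesis that respects intraspecific niche variation. Ensembles across
cross-validation runs, threshold rules and GCMs are combined by majority
consensus: a cell is occupied when at least a set fraction (default 50 %) of
member binary maps vote for it. Climate-change exposure is summarized by the
range-change index

    RC = 100 * (RG - RL) / CPR

where RG counts cells gained (unsuitable now, suitable in the future), RL
cells lost, and CPR the current potential range, all over the jointly valid
cell universe. RC = -100 means complete loss; unlimited dispersal is assumed.

``run_species_analysis`` chains the full study design for one species:
thinning, harmonized PCA, niche overlap and similarity per buffer, SDM
cross-validation for the species / core / disjunct datasets, per-rule
binarization, aggregate construction, per-RCP consensus, and the range-change
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .env_space import EnvGrid, EnvProjection, occurrence_density, pooled_pca
from .evaluation import (BinaryMap, EvalScores, aggregate_scores, binarize,
                         model_sensitivity, roc_auc, select_threshold,
                         sensitivity_specificity)
from .niche_metrics import schoener_d, similarity_test
from .occurrence_prep import build_background, thin_occurrences
from .sdm_core import cross_validate, predict_suitability, sample_pseudoabsences
from .synthetic_landscape import OccurrenceTable, ScenarioSet

__all__ = [
    "ConsensusMap",
    "RangeChangeResult",
    "CPRZeroError",
    "PipelineStageError",
    "MODEL_TYPES",
    "aggregate_union",
    "consensus",
    "range_change",
    "run_species_analysis",
    "SpeciesAnalysisResult",
]

MODEL_TYPES = ("species", "core", "disjunct", "aggregate")


class CPRZeroError(ValueError):
    """Range change is undefined when the current potential range is empty."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ConsensusMap:
    """Per-cell vote fractions and the majority-consensus binary map."""

    scenario_id: str
    votes: np.ndarray  # fraction of members voting 1; NaN on nodata
    consensus: BinaryMap
    fraction: float
    n_members: int

    def __post_init__(self) -> None:
        v = self.votes[np.isfinite(self.votes)]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("votes must lie in [0, 1]")


@dataclass(frozen=True)
class RangeChangeResult:
    model_type: str
    rcp_id: str
    RG: int
    RL: int
    CPR: int
    RC: float

    def __post_init__(self) -> None:
        if min(self.RG, self.RL, self.CPR) < 0 or self.RL > self.CPR:
            raise ValueError("inconsistent range-change cell counts")


def aggregate_union(core_bin: BinaryMap, disjunct_bin: BinaryMap) -> BinaryMap:
    """Cellwise union of the core and disjunct binary maps (aggregate model)."""
    if core_bin.values.shape != disjunct_bin.values.shape:
        raise ValueError("binary maps live on different grids")
    if core_bin.scenario_id != disjunct_bin.scenario_id:
        raise ValueError("binary maps belong to different scenarios")
    a, b = core_bin.values, disjunct_bin.values
    valid = np.isfinite(a) & np.isfinite(b)
    out = np.where(valid, ((a == 1.0) | (b == 1.0)).astype(float), np.nan)
    return BinaryMap(core_bin.scenario_id, out, threshold_rule="aggregate")


def consensus(members: Sequence[BinaryMap], fraction: float = 0.5,
              scenario_id: str | None = None) -> ConsensusMap:
    """Majority-consensus ensemble of binary maps.

    ``votes`` is the per-cell mean of member values; the consensus map marks a
    cell suitable when votes >= ``fraction`` ("at least 50 %" by default).
    """
    if not members:
        raise ValueError("consensus of an empty member list is undefined")
    acc = _VoteAccumulator()
    for m in members:
        acc.add(m)
    return acc.finalize(fraction, scenario_id or members[0].scenario_id)


class _VoteAccumulator:
    """Streaming vote counter so large ensembles need not be held in memory."""

    def __init__(self) -> None:
        self._sum: np.ndarray | None = None
        self._valid: np.ndarray | None = None
        self.n = 0

    def add(self, m: BinaryMap) -> None:
        v = np.nan_to_num(m.values)
        ok = np.isfinite(m.values)
        if self._sum is None:
            self._sum = v.copy()
            self._valid = ok.copy()
        else:
            if v.shape != self._sum.shape:
                raise ValueError("member binary maps live on different grids")
            self._sum += v
            self._valid &= ok
        self.n += 1

    def finalize(self, fraction: float, scenario_id: str) -> ConsensusMap:
        if self.n == 0:
            raise ValueError("consensus of an empty member list is undefined")
        votes = np.where(self._valid, self._sum / self.n, np.nan)
        cons = np.where(self._valid, (votes >= fraction).astype(float), np.nan)
        return ConsensusMap(scenario_id, votes,
                            BinaryMap(scenario_id, cons, "consensus", fraction),
                            fraction, self.n)


def range_change(current: BinaryMap, future: BinaryMap,
                 model_type: str = "", rcp_id: str = "") -> RangeChangeResult:
    """Range-change index between a current and a future binary map.

    Counts are taken over cells valid in both maps, so RC compares a constant
    cell universe. Raises :class:`CPRZeroError` when no cell is currently
    suitable (RC undefined), rather than returning NaN.
    """
    if current.values.shape != future.values.shape:
        raise ValueError("current and future maps live on different grids")
    valid = np.isfinite(current.values) & np.isfinite(future.values)
    cur = (current.values == 1.0) & valid
    fut = (future.values == 1.0) & valid
    cpr = int(cur.sum())
    if cpr == 0:
        raise CPRZeroError("current potential range is empty; RC undefined")
    rg = int((fut & ~cur).sum())
    rl = int((cur & ~fut).sum())
    return RangeChangeResult(model_type, rcp_id, rg, rl, cpr,
                             100.0 * (rg - rl) / cpr)


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

@dataclass
class SpeciesAnalysisResult:
    """Full results bundle of one species' analysis."""

    species: str
    thinned: OccurrenceTable
    projection: EnvProjection
    niche_table: pd.DataFrame
    eval_table: pd.DataFrame
    range_change_table: pd.DataFrame
    current_consensus: dict[str, ConsensusMap] = field(default_factory=dict)
    future_consensus: dict[tuple[str, str], ConsensusMap] = field(default_factory=dict)
    scores: dict[str, EvalScores] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    return [int(c.generate_state(1)[0] % (2**31))
            for c in np.random.SeedSequence(seed).spawn(n)]


def run_species_analysis(scenarios: ScenarioSet, occurrences: OccurrenceTable,
                         config: PipelineConfig | None = None
                         ) -> SpeciesAnalysisResult:
    """Run the whole analysis chain for one species.

    Every random stage is seeded from ``config.seed`` via a deterministic
    seed-spawning scheme and echoed in ``run_log``; any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    cfg = config or PipelineConfig()
    current = scenarios.current
    geom = current.geometry
    species = (occurrences.df["species"].iloc[0]
               if len(occurrences) else (cfg.species or "species"))
    seed_thin, seed_niche, seed_pa, seed_cv = _spawn_seeds(cfg.seed, 4)
    log: dict = {"seed": cfg.seed, "config": cfg.to_dict(),
                 "stage_seeds": {"thin": seed_thin, "niche": seed_niche,
                                 "pseudoabsence": seed_pa, "cv": seed_cv}}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, et, ev, tb):
                if et is not None and not issubclass(et, PipelineStageError):
                    raise PipelineStageError(f"stage '{name}' failed: {ev}") from ev
        return _Ctx()

    with stage("thinning"):
        thinned = thin_occurrences(occurrences, geom.cellsize_km, seed_thin, geom)

    with stage("pooled_pca"):
        proj = pooled_pca(scenarios)
        cur_id = current.scenario_id
        occ_scores = {}
        for group in ("species", "core", "disjunct"):
            sub = thinned.subset(group)
            if len(sub):
                r, c = sub.rowcols(geom)
                occ_scores[group] = proj.scores_at_cells(cur_id, r, c)

    # -- niche analysis in environmental space -----------------------------
    niche_rows = []
    if cfg.run_niche_analysis:
        with stage("niche_analysis"):
            sim_seeds = iter(_spawn_seeds(seed_niche, 2 * len(cfg.buffers_km)))
            for buffer_km in cfg.buffers_km:
                bg, bg_sc = {}, {}
                for group in ("core", "disjunct"):
                    bg[group] = build_background(thinned.subset(group), current,
                                                 buffer_km, group=group)
                    bg_sc[group] = proj.background_scores(cur_id, bg[group].cells)
                grid = EnvGrid.from_scores([bg_sc["core"], bg_sc["disjunct"]],
                                           R=cfg.env_grid_R)
                z = {g: occurrence_density(occ_scores[g], bg_sc[g], grid, group=g,
                                           correction=cfg.occupancy_correction)
                     for g in ("core", "disjunct")}
                D = schoener_d(z["core"], z["disjunct"]).D
                for focal, other in (("core", "disjunct"), ("disjunct", "core")):
                    res = similarity_test(
                        occ_scores[focal], bg_sc[focal], occ_scores[other],
                        bg_sc[other], reps=cfg.similarity_reps, alpha=cfg.alpha,
                        seed=next(sim_seeds), grid=grid,
                        correction=cfg.occupancy_correction,
                        direction=f"{focal}_vs_{other}")
                    niche_rows.append({
                        "species": species, "buffer_km": buffer_km,
                        "direction": res.direction, "D": D,
                        "p_more": res.p_more, "p_less": res.p_less,
                        "verdict": res.verdict})
    niche_table = pd.DataFrame(niche_rows)

    # -- species distribution modelling ------------------------------------
    eval_rows, rc_rows = [], []
    scores_by_type: dict[str, EvalScores] = {}
    cur_cons: dict[str, ConsensusMap] = {}
    fut_cons: dict[tuple[str, str], ConsensusMap] = {}
    sens_by_type: dict[str, float] = {}
    if cfg.run_sdm:
        with stage("sdm"):
            pa_seeds = _spawn_seeds(seed_pa, cfg.n_pa_sets)
            cv_seeds = _spawn_seeds(seed_cv, 3 * cfg.n_pa_sets)
            bg_sets = []
            for s in pa_seeds:
                pa = sample_pseudoabsences(current, cfg.n_background, s)
                bg_sets.append(proj.scores_at_cells(
                    cur_id, pa["row"].to_numpy(), pa["col"].to_numpy()))

            future_keys = sorted(scenarios.futures)
            cv_iter = iter(cv_seeds)
            per_type_future_acc: dict[str, dict[str, _VoteAccumulator]] = {}
            for mtype in ("species", "core", "disjunct"):
                auc_list, tss_list = [], []
                acc_cur = _VoteAccumulator()
                acc_fut = {rcp: _VoteAccumulator() for rcp in scenarios.rcp_ids}
                for bg in bg_sets:
                    runs = cross_validate(occ_scores[mtype], bg, cfg.n_cv,
                                          cfg.test_frac, seed=next(cv_iter))
                    for run in runs:
                        ts = np.concatenate([run.model.predict(run.test_presences),
                                             run.model.predict(run.test_background)])
                        tl = np.concatenate([np.ones(len(run.test_presences)),
                                             np.zeros(len(run.test_background))])
                        auc_list.append(roc_auc(ts, tl))
                        thresholds = {rule: select_threshold(ts, tl, rule)
                                      for rule in cfg.threshold_rules}
                        t_tss = thresholds.get("MaxSensSpec",
                                               next(iter(thresholds.values())))
                        sn, sp = sensitivity_specificity(ts, tl, t_tss)
                        tss_list.append(sn + sp - 1.0)
                        smaps = {cur_id: predict_suitability(
                            run.model, proj.scores[cur_id], cur_id)}
                        for gcm, rcp in future_keys:
                            sid = scenarios.futures[(gcm, rcp)].scenario_id
                            smaps[(gcm, rcp)] = predict_suitability(
                                run.model, proj.scores[sid], sid)
                        for rule, thr in thresholds.items():
                            acc_cur.add(binarize(smaps[cur_id], thr, rule))
                            for gcm, rcp in future_keys:
                                acc_fut[rcp].add(binarize(smaps[(gcm, rcp)], thr, rule))
                scores_by_type[mtype] = EvalScores(mtype, np.array(auc_list),
                                                   np.array(tss_list))
                cur_cons[mtype] = acc_cur.finalize(cfg.consensus_fraction, cur_id)
                for rcp, acc in acc_fut.items():
                    fut_cons[(mtype, rcp)] = acc.finalize(cfg.consensus_fraction, rcp)

            scores_by_type["aggregate"] = aggregate_scores(
                scores_by_type["core"], scores_by_type["disjunct"])
            agg_cur = aggregate_union(cur_cons["core"].consensus,
                                      cur_cons["disjunct"].consensus)
            cur_cons["aggregate"] = ConsensusMap(
                cur_id, agg_cur.values, agg_cur, cfg.consensus_fraction, 2)
            for rcp in scenarios.rcp_ids:
                agg_fut = aggregate_union(fut_cons[("core", rcp)].consensus,
                                          fut_cons[("disjunct", rcp)].consensus)
                fut_cons[("aggregate", rcp)] = ConsensusMap(
                    rcp, agg_fut.values, agg_fut, cfg.consensus_fraction, 2)

        with stage("evaluation_table"):
            for mtype in MODEL_TYPES:
                sc = scores_by_type[mtype]
                sens = model_sensitivity(cur_cons[mtype].consensus, thinned, geom)
                sens_by_type[mtype] = sens
                eval_rows.append({
                    "species": species, "model_type": mtype,
                    "auc_mean": sc.auc_mean, "auc_sd": sc.auc_sd,
                    "tss_mean": sc.tss_mean, "tss_sd": sc.tss_sd,
                    "sensitivity_pct": sens})

        with stage("range_change"):
            for mtype in MODEL_TYPES:
                for rcp in scenarios.rcp_ids:
                    rc = range_change(cur_cons[mtype].consensus,
                                      fut_cons[(mtype, rcp)].consensus,
                                      model_type=mtype, rcp_id=rcp)
                    rc_rows.append({
                        "species": species, "model_type": mtype, "rcp": rcp,
                        "RG": rc.RG, "RL": rc.RL, "CPR": rc.CPR, "RC": rc.RC})

    return SpeciesAnalysisResult(
        species=species, thinned=thinned, projection=proj,
        niche_table=niche_table,
        eval_table=pd.DataFrame(eval_rows),
        range_change_table=pd.DataFrame(rc_rows),
        current_consensus=cur_cons, future_consensus=fut_cons,
        scores=scores_by_type, run_log=log)
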