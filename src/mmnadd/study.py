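"""End-to-end study runs and validation experiments.

``run_study`` reproduces the structure of the experiment on synthetic
cohorts: paradigm generation, simulation of both groups, preprocessing,
empirical/modeled MMNm construction, grand-average sensor selection, and the
three families of cluster-based permutation tests (presence of the MMNm,
ordering of single/double/triple responses, and the additivity-by-expertise
interaction with its simple effects).

The validation experiments characterize the statistical machinery itself on
the generative model: ``type1_experiment`` estimates the false-positive rate
of the interaction test under equal-kappa cohorts, ``power_experiment``
traces detection probability against the ground-truth subadditivity
coefficient, and ``kappa_recovery`` measures bias/RMSE of the kappa
estimator (a split-half cross-validated inner-product ratio between
empirical and modeled waves).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .mmn import (
    MMNmWave,
    SensorSelection,
    empirical_mmnm,
    grand_average,
    modeled_mmnm,
    select_peak_sensors,
)
from .paradigm import (
    BlockSequence,
    DeviantType,
    generate_complex_block,
    generate_simple_block,
    mark_analysis_standards,
    paradigm_trial_table,
)
from .preprocess import (
    Evoked,
    PreprocessParams,
    average_condition,
    bandpass,
    baseline_correct,
    combine_planar,
    reject_jumps,
)
from .simulate import (
    GROUPS,
    EpochSet,
    SensorLayout,
    SimulationConfig,
    default_kappa,
    inject_jumps,
    make_layout,
    simulate_subject,
    simulate_subject_means,
)
from .stats import (
    ORDERING_PAIRS,
    TestSpec,
    bonferroni_alpha,
    build_adjacency,
    interaction_test,
    ordering_test,
    presence_test,
    simple_effect_test,
)

N_BLOCKS = {"complex": 4, "simple": 3}


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    """Full configuration of one synthetic study run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    test: TestSpec = field(default_factory=TestSpec)
    paradigms: tuple[str, ...] = ("complex", "simple")
    kappa_by_paradigm: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "complex": default_kappa(),
            "simple": {g: {} for g in GROUPS},
        }
    )
    n_blocks: dict[str, int] = field(default_factory=lambda: dict(N_BLOCKS))
    master_seed: int = 0

    @classmethod
    def scaled(cls, master_seed: int = 0) -> "StudyConfig":
        """A reduced preset that finishes in seconds: fewer subjects, trials,
        sensors, and permutations; same effect sizes and noise level."""
        return cls(
            sim=SimulationConfig(
                n_subjects_per_group=6, trials_per_deviant=48, n_pairs=24
            ),
            test=TestSpec(n_perm=200),
            master_seed=master_seed,
        )


def _preprocess_fast(
    epochs: EpochSet, params: PreprocessParams, reject: bool = True,
    combine: bool = True,
) -> tuple[dict[DeviantType, Evoked], float]:
    """Cleaning chain with filtering applied to condition averages.

    Band-pass filtering and trial averaging are both linear, so they commute;
    filtering the per-condition averages gives the same evokeds as filtering
    every trial at a fraction of the cost.  Jump rejection still sees the raw
    trials (skipped for containers that already hold condition means).
    """
    if reject and not epochs.meta.get("collapsed", False):
        clean, report = reject_jumps(epochs, params.z_cutoff)
        frac = report.retained_fraction
    else:
        clean, frac = epochs, 1.0
    evokeds: dict[DeviantType, Evoked] = {}
    for cond in DeviantType:
        mask = clean.condition == cond.value
        if cond is DeviantType.STD:
            mask &= clean.is_analysis_standard
        if not mask.any():
            continue
        ev = average_condition(clean, cond)
        avg = EpochSet(
            data=ev.data[None],
            channel_names=ev.channel_names,
            fs_hz=ev.fs_hz,
            t0_s=ev.t0_s,
            condition=np.array([cond.value], dtype=object),
            is_analysis_standard=np.array([cond is DeviantType.STD]),
            subject_id=ev.subject_id,
            group=ev.group,
            paradigm=ev.paradigm,
        )
        avg = bandpass(avg, params.low_hz, params.high_hz, params.filter_order, params.pad_s)
        ev.data = avg.data[0]
        if combine:
            ev = combine_planar(ev, params.combine_convention)
        evokeds[cond] = baseline_correct(ev, params.baseline_s)
    return evokeds, frac


def build_mmnms(evokeds: dict[DeviantType, Evoked]) -> list[MMNmWave]:
    """Empirical MMNms for every deviant present, and modeled MMNms for every
    double/triple whose constituent singles are present."""
    std = evokeds[DeviantType.STD]
    waves: list[MMNmWave] = []
    empirical: dict[DeviantType, MMNmWave] = {}
    for dev in DeviantType.deviants():
        if dev in evokeds:
            w = empirical_mmnm(evokeds[dev], std)
            empirical[dev] = w
            waves.append(w)
    for combo in DeviantType.combinations():
        if combo in evokeds and all(f in empirical for f in combo.constituents):
            waves.append(modeled_mmnm([empirical[f] for f in combo.constituents]))
    return waves


@dataclass
class CohortData:
    paradigm: str
    evokeds: list[Evoked]
    mmnms: list[MMNmWave]
    retained: dict[str, float]  # subject_id -> retained trial fraction


def simulate_cohort(
    sim_cfg: SimulationConfig,
    layout: SensorLayout,
    paradigm: str,
    pp: PreprocessParams,
    seed_seq: np.random.SeedSequence,
    inject_artifacts: bool = True,
    use_means: bool = False,
) -> CohortData:
    """Simulate and preprocess both groups for one paradigm.

    With ``use_means`` the per-condition trial averages are drawn directly
    (see ``simulate_subject_means``); otherwise full trial sets are
    simulated, optionally contaminated with jump artifacts, and cleaned.
    """
    evokeds: list[Evoked] = []
    mmnms: list[MMNmWave] = []
    retained: dict[str, float] = {}
    children = seed_seq.spawn(2 * sim_cfg.n_subjects_per_group)
    k = 0
    for group in GROUPS:
        for s in range(sim_cfg.n_subjects_per_group):
            sid = f"{group[:3]}{s:02d}"
            child = children[k]
            k += 1
            if use_means:
                epochs = simulate_subject_means(
                    sim_cfg, layout, group, _child_seed(child), subject_id=sid,
                    paradigm=paradigm,
                )
            else:
                epochs = simulate_subject(
                    sim_cfg, layout, group, _child_seed(child), subject_id=sid,
                    paradigm=paradigm,
                )
                if inject_artifacts and sim_cfg.artifact.p_jump > 0:
                    epochs = inject_jumps(
                        epochs, sim_cfg.artifact.p_jump, sim_cfg.artifact.amplitude,
                        _child_seed(child.spawn(1)[0]),
                    )
            evk, frac = _preprocess_fast(epochs, pp)
            retained[f"{paradigm}_{sid}"] = frac
            evokeds.extend(evk.values())
            mmnms.extend(build_mmnms(evk))
    return CohortData(paradigm, evokeds, mmnms, retained)


@dataclass
class StudyReport:
    """Machine twin of the study's result tables."""

    trial_table: pd.DataFrame
    presence: pd.DataFrame  # table-2-like
    ordering: pd.DataFrame  # table-3-like
    additivity: pd.DataFrame  # table-4-like
    selection: SensorSelection
    retained: dict[str, float]
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trial_table.to_csv(out / "trial_table.csv", index=False)
        self.presence.to_csv(out / "presence.csv", index=False)
        self.ordering.to_csv(out / "ordering.csv", index=False)
        self.additivity.to_csv(out / "additivity.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "selection": self.selection.to_dict(),
            "retained_fraction": self.retained,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the complete analysis chain on synthetic cohorts.

    Presence and ordering tests are one-sided validity checks at alpha 0.05
    (uncorrected); the four interaction tests use the Bonferroni-corrected
    per-tail alpha 0.025/4 = 0.00625; simple effects of additivity are
    reported per group at per-tail alpha 0.025.
    """
    ss = np.random.SeedSequence(config.master_seed)
    ss_layout, ss_blocks, ss_sim, ss_tests = ss.spawn(4)
    layout = make_layout(config.sim.n_pairs, seed=_child_seed(ss_layout))

    blocks: list[BlockSequence] = []
    block_seeds = ss_blocks.spawn(sum(config.n_blocks[p] for p in config.paradigms))
    bi = 0
    for paradigm in config.paradigms:
        gen = generate_complex_block if paradigm == "complex" else generate_simple_block
        for b in range(config.n_blocks[paradigm]):
            blk = gen(f"{paradigm[0].upper()}{b + 1}", _child_seed(block_seeds[bi]))
            blocks.append(mark_analysis_standards(blk))
            bi += 1
    trial_table = paradigm_trial_table(blocks)

    cohorts: dict[str, CohortData] = {}
    sim_seeds = ss_sim.spawn(len(config.paradigms))
    for i, paradigm in enumerate(config.paradigms):
        sim_cfg = replace(config.sim, kappa=config.kappa_by_paradigm[paradigm])
        cohorts[paradigm] = simulate_cohort(
            sim_cfg, layout, paradigm, config.preprocess, sim_seeds[i]
        )

    all_empirical = [
        w for c in cohorts.values() for w in c.mmnms if w.kind == "empirical"
    ]
    grand = grand_average(all_empirical)
    selection = select_peak_sensors(grand, layout)
    adjacency = build_adjacency(layout, selection)

    test_seed_root = ss_tests
    counter = [0]

    def next_spec(**kw) -> TestSpec:
        counter[0] += 1
        seed = _child_seed(test_seed_root.spawn(1)[0])
        return replace(config.test, seed=seed, **kw)

    alpha_presence = 0.05
    presence_rows = []
    for paradigm in config.paradigms:
        for group in GROUPS:
            for dev in DeviantType.deviants():
                res = presence_test(
                    cohorts[paradigm].evokeds, dev, group,
                    next_spec(tails="pos"), selection, adjacency,
                )
                p = res.min_p()
                presence_rows.append(
                    {
                        "paradigm": paradigm, "group": group,
                        "deviant_type": dev.value, "p": p,
                        "alpha": alpha_presence,
                        "significant": p <= alpha_presence,
                        "maxsum": res.observed["pos"],
                    }
                )
    presence = pd.DataFrame(presence_rows)

    ordering_rows = []
    for paradigm in config.paradigms:
        for larger, smaller in ORDERING_PAIRS:
            res = ordering_test(
                cohorts[paradigm].mmnms, DeviantType(larger), DeviantType(smaller),
                next_spec(tails="pos"), selection, adjacency,
            )
            p = res.min_p()
            ordering_rows.append(
                {
                    "paradigm": paradigm, "comparison": f"{larger} > {smaller}",
                    "p": p, "alpha": alpha_presence,
                    "significant": p <= alpha_presence,
                    "maxsum": res.observed["pos"],
                }
            )
    ordering = pd.DataFrame(ordering_rows)

    alpha_interaction = bonferroni_alpha(0.05, 4)
    alpha_simple = 0.025
    additivity_rows = []
    for paradigm in config.paradigms:
        for combo in DeviantType.combinations():
            res = interaction_test(
                cohorts[paradigm].mmnms, combo, next_spec(), selection, adjacency
            )
            p_int = res.min_p()
            row = {
                "paradigm": paradigm, "deviant_type": combo.value,
                "interaction_p": p_int, "interaction_alpha": alpha_interaction,
                "interaction_significant": p_int <= alpha_interaction,
            }
            for group in GROUPS:
                sres = simple_effect_test(
                    cohorts[paradigm].mmnms, combo, group, next_spec(),
                    selection, adjacency,
                )
                sp = sres.min_p()
                row[f"simple_p_{group}"] = sp
                row[f"simple_significant_{group}"] = sp <= alpha_simple
            row["simple_alpha"] = alpha_simple
            additivity_rows.append(row)
    additivity = pd.DataFrame(additivity_rows)

    retained = {}
    for c in cohorts.values():
        retained.update(c.retained)
    report = StudyReport(
        trial_table=trial_table,
        presence=presence,
        ordering=ordering,
        additivity=additivity,
        selection=selection,
        retained=retained,
        provenance={
            "master_seed": config.master_seed,
            "n_subjects_per_group": config.sim.n_subjects_per_group,
            "trials_per_deviant": config.sim.trials_per_deviant,
            "n_pairs": config.sim.n_pairs,
            "n_perm": config.test.n_perm,
            "paradigms": list(config.paradigms),
            "kappa_by_paradigm": config.kappa_by_paradigm,
            "adjacency_threshold_m": adjacency.distance_threshold_m,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# Validation experiments
# ---------------------------------------------------------------------------

def _experiment_config(
    base: SimulationConfig,
    kappa: dict[str, dict[str, float]],
    conditions: Sequence[DeviantType],
) -> SimulationConfig:
    cfg = replace(base, kappa=kappa, conditions=tuple(conditions))
    # artifact-free cohorts: the rejection stage is validated separately
    cfg = replace(cfg, artifact=replace(cfg.artifact, p_jump=0.0))
    return cfg


def _conditions_for(combos: Sequence[DeviantType]) -> list[DeviantType]:
    feats: set[DeviantType] = set()
    for c in combos:
        feats |= c.constituents
    return [DeviantType.STD, *sorted(feats, key=lambda d: d.value), *combos]


def _interaction_result(
    sim_cfg: SimulationConfig,
    layout: SensorLayout,
    pp: PreprocessParams,
    combos: Sequence[DeviantType],
    n_perm: int,
    seed_seq: np.random.SeedSequence,
) -> dict[DeviantType, float]:
    """Simulate one cohort replicate and return interaction min-p per combo."""
    cohort = simulate_cohort(sim_cfg, layout, "complex", pp, seed_seq.spawn(1)[0],
                             inject_artifacts=False, use_means=True)
    grand = grand_average([w for w in cohort.mmnms if w.kind == "empirical"])
    selection = select_peak_sensors(grand, layout)
    adjacency = build_adjacency(layout, selection)
    out = {}
    for combo in combos:
        spec = TestSpec(
            design="independent", n_perm=n_perm,
            seed=_child_seed(seed_seq.spawn(1)[0]),
        )
        res = interaction_test(cohort.mmnms, combo, spec, selection, adjacency)
        out[combo] = res.min_p()
    return out


def _binom_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval."""
    a = (1.0 - conf) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


@dataclass
class Type1Result:
    rate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    alpha: float
    n_perm: int


def type1_experiment(
    config: SimulationConfig,
    n_replicates: int = 200,
    reduced_nperm: int = 500,
    deviant_type: DeviantType = DeviantType.FI,
    alpha: float = 0.05,
    seed: int = 0,
    pp: PreprocessParams | None = None,
) -> Type1Result:
    """False-positive rate of the interaction test under equal-kappa groups.

    The groups share the configured kappa (the caller's config is forced to
    the null by copying the first group's kappa to both); a replicate counts
    as a false positive when any interaction cluster reaches the per-tail
    level alpha/2 (overall two-sided alpha).
    """
    null_kappa = {g: dict(config.kappa.get(GROUPS[0], {})) for g in GROUPS}
    sim_cfg = _experiment_config(config, null_kappa, _conditions_for([deviant_type]))
    pp = pp or PreprocessParams()
    ss = np.random.SeedSequence(seed)
    layout = make_layout(sim_cfg.n_pairs, seed=_child_seed(ss.spawn(1)[0]))
    hits = 0
    for _ in range(n_replicates):
        ps = _interaction_result(sim_cfg, layout, pp, [deviant_type], reduced_nperm, ss.spawn(1)[0])
        hits += ps[deviant_type] <= alpha / 2.0
    lo, hi = _binom_ci(hits, n_replicates)
    return Type1Result(hits / n_replicates, lo, hi, n_replicates, alpha, reduced_nperm)


def power_experiment(
    config: SimulationConfig,
    kappa_grid: Sequence[float] = (0.0, 0.2, 0.4),
    n_replicates: int = 20,
    deviant_types: Sequence[DeviantType] = (DeviantType.FI, DeviantType.IL, DeviantType.LF),
    reduced_nperm: int = 500,
    alpha: float = bonferroni_alpha(0.05, 4),
    seed: int = 0,
    pp: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Interaction-detection probability against the kappa group difference.

    The feature-selective default is retained: at each grid value the
    musician group receives that kappa for frequency-containing combinations
    (FI, LF, FIL) while IL and the non-musician group stay at zero.  Common
    random numbers are used across grid values.
    """
    pp = pp or PreprocessParams()
    rows = []
    base_ss = np.random.SeedSequence(seed)
    layout = make_layout(config.n_pairs, seed=_child_seed(base_ss.spawn(1)[0]))
    rep_seeds = [_child_seed(e) for e in base_ss.spawn(n_replicates)]
    for kval in kappa_grid:
        kappa = {
            "musician": {"FI": kval, "LF": kval, "FIL": kval},
            "nonmusician": {},
        }
        sim_cfg = _experiment_config(config, kappa, _conditions_for(list(deviant_types)))
        detect = {d: 0 for d in deviant_types}
        for r in range(n_replicates):
            ps = _interaction_result(
                sim_cfg, layout, pp, list(deviant_types), reduced_nperm,
                np.random.SeedSequence(rep_seeds[r]),
            )
            for d in deviant_types:
                detect[d] += ps[d] <= alpha
        for d in deviant_types:
            rows.append(
                {
                    "deviant_type": d.value, "kappa": kval,
                    "power": detect[d] / n_replicates,
                    "n_replicates": n_replicates, "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kappa recovery
# ---------------------------------------------------------------------------

def _split_half(epochs: EpochSet) -> tuple[EpochSet, EpochSet]:
    """Odd/even split within each condition (analysis standards included)."""
    idx_a, idx_b = [], []
    for cond in np.unique(epochs.condition.astype(str)):
        idx = np.flatnonzero(epochs.condition == cond)
        idx_a.extend(idx[0::2])
        idx_b.extend(idx[1::2])
    halves = []
    for sel in (np.sort(idx_a), np.sort(idx_b)):
        halves.append(
            replace(
                epochs,
                data=epochs.data[sel],
                condition=epochs.condition[sel],
                is_analysis_standard=epochs.is_analysis_standard[sel],
                meta=dict(epochs.meta),
            )
        )
    return halves[0], halves[1]


def estimate_kappa(
    subject_maps: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
) -> float:
    """Group-level subadditivity estimate from split-half map quadruples.

    Each entry holds (empirical_1, empirical_2, modeled_1, modeled_2)
    difference maps built from disjoint trial halves, already restricted to
    the analysis channels and window.  The maps are first averaged across
    subjects (suppressing subject-level noise quadratics), then
    kappa_hat = 1 - (<emp_1, mod_2> + <emp_2, mod_1>) / (2 <mod_1, mod_2>):
    the cross-half inner products cancel the noise terms that would
    otherwise attenuate (modeled autocovariance) or inflate (shared standard
    average) the ratio.
    """
    e1 = np.mean([q[0] for q in subject_maps], axis=0)
    e2 = np.mean([q[1] for q in subject_maps], axis=0)
    m1 = np.mean([q[2] for q in subject_maps], axis=0)
    m2 = np.mean([q[3] for q in subject_maps], axis=0)
    num = float((e1 * m2).sum() + (e2 * m1).sum())
    den = 2.0 * float((m1 * m2).sum())
    if den == 0:
        raise ValueError("degenerate modeled waves: zero cross-half energy")
    return 1.0 - num / den


def _restrict(data: np.ndarray, rows: np.ndarray, tmask: np.ndarray) -> np.ndarray:
    return data[np.ix_(rows, np.flatnonzero(tmask))]


def _subject_half_maps(
    epochs: EpochSet,
    combo: DeviantType,
    pp: PreprocessParams,
    rows: np.ndarray,
    tmask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split-half empirical/modeled difference maps on the linear scale.

    The estimator works on the *uncombined* gradiometer channels, where the
    additive model is exactly linear: the planar RMS stage would otherwise
    rectify noise into a signal-dependent bias.  Accepts a full trial
    container (odd/even split) or a collapsed half-mean container from
    ``simulate_subject_means(halves=True)``.
    """
    if epochs.meta.get("collapsed", False):
        half_ids = np.asarray(epochs.meta["half"])
        halves = []
        for h in (0, 1):
            sel = half_ids == h
            halves.append(
                replace(
                    epochs,
                    data=epochs.data[sel],
                    condition=epochs.condition[sel],
                    is_analysis_standard=epochs.is_analysis_standard[sel],
                    meta=dict(epochs.meta),
                )
            )
        half_a, half_b = halves
    else:
        half_a, half_b = _split_half(epochs)
    out = []
    for half in (half_a, half_b):
        evk, _ = _preprocess_fast(half, pp, reject=False, combine=False)
        std = evk[DeviantType.STD].data
        emp = evk[combo].data - std
        mod = sum(evk[f].data - std for f in combo.constituents)
        out.append((_restrict(emp, rows, tmask), _restrict(mod, rows, tmask)))
    (e1, m1), (e2, m2) = out
    return e1, e2, m1, m2


def kappa_recovery(
    config: SimulationConfig,
    n_replicates: int = 8,
    trial_counts: Sequence[int] = (72, 144, 288),
    combo: DeviantType = DeviantType.FI,
    group: str = "musician",
    seed: int = 0,
    pp: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Bias and RMSE of the kappa estimator against trial count.

    Simulates cohorts of the given group at each trial count, estimates
    kappa per replicate from split-half empirical/modeled waves over the
    analysis selection, and tabulates mean estimate, bias and RMSE.
    """
    pp = pp or PreprocessParams()
    sim_cfg = _experiment_config(config, config.kappa, _conditions_for([combo]))
    true_k = sim_cfg.kappa_for(group, combo)
    ss = np.random.SeedSequence(seed)
    layout = make_layout(sim_cfg.n_pairs, seed=_child_seed(ss.spawn(1)[0]))
    # fixed hotspot-based selection: built from the noise-free evoked field
    clean = replace(sim_cfg, noise=replace(sim_cfg.noise, sigma=0.0, subject_cv=0.0))
    probe = simulate_subject(clean, layout, group, 0, trial_plan={combo: 1, DeviantType.STD: 1})
    evk, _ = _preprocess_fast(probe, pp)
    grand = empirical_mmnm(evk[combo], evk[DeviantType.STD])
    selection = select_peak_sensors(grand, layout)
    chan_rows = np.sort(
        np.concatenate([[2 * p, 2 * p + 1] for p in selection.all_pairs])
    )
    tmask = (grand.times() >= selection.window_s[0]) & (
        grand.times() <= selection.window_s[1]
    )

    rows = []
    for n_trials in trial_counts:
        cfg_n = replace(sim_cfg, trials_per_deviant=int(n_trials))
        estimates = []
        for _ in range(n_replicates):
            rep_ss = ss.spawn(1)[0]
            quadruples = []
            for s in range(cfg_n.n_subjects_per_group):
                child = rep_ss.spawn(1)[0]
                epochs = simulate_subject_means(
                    cfg_n, layout, group, _child_seed(child),
                    subject_id=f"S{s:02d}", halves=True,
                )
                quadruples.append(
                    _subject_half_maps(epochs, combo, pp, chan_rows, tmask)
                )
            estimates.append(estimate_kappa(quadruples))
        est = np.asarray(estimates)
        rows.append(
            {
                "combo": combo.value, "group": group, "n_trials": int(n_trials),
                "true_kappa": true_k, "mean_estimate": float(est.mean()),
                "bias": float(est.mean() - true_k),
                "rmse": float(np.sqrt(np.mean((est - true_k) ** 2))),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
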