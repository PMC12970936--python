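"""Synthetic two-cohort mediator datasets with known ground truth.

The generator emulates the structure of a two-study sputum biomarker design:
6-7 participant groups of 20-30 each split across 2 study batches, lognormal
mediator concentrations (multivariate normal on the log2 scale) with
group-specific mean shifts, block co-correlation among functionally related
mediators, additive + multiplicative batch effects on the log2 scale, and
left-censoring at per-mediator limits of detection.

Every downstream stage of the pipeline is testable against the
:class:`GroundTruth` emitted alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sputumpanel.containers import MediatorMatrix
from sputumpanel.panel import CHEMOTACTIC, INFLAMMATORY, PANEL, PROTEASES_ENZYMES


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


@dataclass
class GroupSpec:
    """One participant group: name, size, and per-mediator log2 mean shifts."""

    name: str
    n: int
    shifts: Mapping[str, float] = field(default_factory=dict)


@dataclass
class CovariateSpec:
    """Distributional parameters for one group's covariates."""

    age_mean: float = 50.0
    age_sd: float = 10.0
    p_female: float = 0.5
    bmi_mean: float = 28.0
    bmi_sd: float = 5.0
    p_smoker: float = 0.3
    p_cardiovascular: float = 0.3
    p_pulmonary_vascular: float = 0.1
    p_inhaled_steroid: float = 0.2
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: {"white": 0.7, "black": 0.2, "other": 0.1}
    )


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort draw.

    Parameters
    ----------
    group_specs
        Groups with sizes (each n >= 2) and sparse per-mediator log2 shifts.
    mediator_names
        Panel identifiers; defaults to the 27-mediator sputum panel.
    correlation_blocks
        ``(members, rho)`` pairs; members are mediator names (or indices) and
        ``rho`` in [0, 1) is the common within-block log2-scale correlation.
        Blocks must be disjoint.
    batch_assignment
        group name -> batch id.  Every group must be assigned.
    batch_additive, batch_multiplicative
        Per-batch location shift (log2 units) and error-scale factor (> 0);
        either a scalar broadcast over mediators or a per-mediator mapping.
    lod_quantile
        Fraction of each mediator's marginal distribution censored at the
        limit of detection; must lie in [0, 0.25].
    noise_sd
        Per-mediator log2-scale residual SD (> 0); scalar or mapping.
    baseline_log2
        Per-mediator grand log2 mean; default spreads the panel over 2..10
        (roughly 4 pg/mL to 1 ng/mL on the concentration scale).
    covariate_model
        group name -> :class:`CovariateSpec`; defaults are filled per group.
    age_slope
        Optional common age -> log2-concentration slope (per year, centred at
        age 50) used to exercise covariate adjustment; default 0.
    seed
        Generator seed; identical configs produce bit-identical output.
    """

    group_specs: Sequence[GroupSpec]
    mediator_names: Sequence[str] = PANEL
    correlation_blocks: Sequence[tuple[Sequence, float]] = ()
    batch_assignment: Mapping[str, str] = field(default_factory=dict)
    batch_additive: Mapping[str, object] = field(default_factory=dict)
    batch_multiplicative: Mapping[str, object] = field(default_factory=dict)
    lod_quantile: float = 0.1
    noise_sd: object = 1.0
    baseline_log2: Mapping[str, float] | None = None
    covariate_model: Mapping[str, CovariateSpec] = field(default_factory=dict)
    age_slope: float = 0.0
    seed: int = 0

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        if not self.group_specs:
            raise ConfigurationError("group_specs: at least one group required")
        names = [g.name for g in self.group_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("group_specs: duplicate group names")
        for g in self.group_specs:
            if g.n < 2:
                raise ConfigurationError(f"group_specs: group {g.name!r} has n={g.n} < 2")
            unknown = set(g.shifts) - set(self.mediator_names)
            if unknown:
                raise ConfigurationError(
                    f"group_specs: group {g.name!r} shifts reference unknown mediators {sorted(unknown)}"
                )
        if not (0.0 <= self.lod_quantile <= 0.25):
            raise ConfigurationError(f"lod_quantile: {self.lod_quantile} outside [0, 0.25]")
        seen: set[int] = set()
        for members, rho in self.correlation_blocks:
            idx = self._block_indices(members)
            if seen & set(idx):
                raise ConfigurationError("correlation_blocks: blocks are not disjoint")
            seen.update(idx)
            if not (0.0 <= rho < 1.0):
                raise ConfigurationError(f"correlation_blocks: rho {rho} outside [0, 1)")
        missing = [n for n in names if n not in self.batch_assignment]
        if self.batch_assignment and missing:
            raise ConfigurationError(f"batch_assignment: groups without a batch: {missing}")
        mult = self._per_batch_mediator(self.batch_multiplicative, default=1.0)
        if (mult.to_numpy() <= 0).any():
            raise ConfigurationError("batch_multiplicative: values must be > 0")
        sd = self._per_mediator(self.noise_sd, "noise_sd")
        if (sd <= 0).any():
            raise ConfigurationError("noise_sd: values must be > 0")

    # -- helpers ------------------------------------------------------- #

    def _block_indices(self, members: Sequence) -> list[int]:
        med = list(self.mediator_names)
        out = []
        for m in members:
            if isinstance(m, (int, np.integer)):
                out.append(int(m))
            else:
                if m not in med:
                    raise ConfigurationError(f"correlation_blocks: unknown mediator {m!r}")
                out.append(med.index(m))
        return out

    def _per_mediator(self, value: object, fieldname: str) -> np.ndarray:
        med = list(self.mediator_names)
        if isinstance(value, Mapping):
            return np.array([float(value.get(m, 1.0)) for m in med])
        try:
            return np.full(len(med), float(value))  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{fieldname}: not a scalar or per-mediator mapping") from exc

    def _per_batch_mediator(self, table: Mapping[str, object], default: float) -> pd.DataFrame:
        batches = sorted(set(self.batch_assignment.values())) or ["batch1"]
        med = list(self.mediator_names)
        out = pd.DataFrame(default, index=batches, columns=med, dtype=float)
        for b, v in table.items():
            if b not in out.index:
                raise ConfigurationError(f"batch effect given for unknown batch {b!r}")
            if isinstance(v, Mapping):
                for m, x in v.items():
                    out.loc[b, m] = float(x)
            else:
                out.loc[b, :] = float(v)
        return out

    def correlation_matrix(self) -> np.ndarray:
        """The target log2-scale correlation matrix implied by the blocks."""
        m = len(self.mediator_names)
        corr = np.eye(m)
        for members, rho in self.correlation_blocks:
            idx = self._block_indices(members)
            for i in idx:
                for j in idx:
                    if i != j:
                        corr[i, j] = rho
        return corr


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    group_log2_means: pd.DataFrame  # group x mediator (baseline + shift, batch-free)
    batch_additive: pd.DataFrame  # batch x mediator
    batch_multiplicative: pd.DataFrame  # batch x mediator
    correlation: np.ndarray  # mediator x mediator, log2 scale
    lod: pd.Series  # per-mediator LOD (concentration units)
    censored: pd.DataFrame  # participant x mediator bool


# ---------------------------------------------------------------------- #
# Default study roster
# ---------------------------------------------------------------------- #

_GOLD3_INFLAMMATORY = ("CRP", "IL-10", "IL12p70", "IL-8", "IP-10", "TNF-a")
_PROTEASE_AXIS = ("MMP-9", "MPO", "NE", "TIMP-1", "TIMP-2")


def default_config(seed: int = 0, lod_quantile: float = 0.1) -> SimConfig:
    """The default two-cohort roster.

    Batch 1 emulates a COPD observational study (pooled control, pre-COPD,
    GOLD 1/2, GOLD 3; 25-29 per group); batch 2 a young-adult e-cigarette
    study (control, 3rd-generation users, 4th-generation users).  Planted
    effects mirror the qualitative pattern the pipeline is meant to detect:
    inflammatory mediators elevated in GOLD 3; the protease/elastase axis
    elevated in pre-COPD and GOLD 3, with a weaker elevation in e-cig users;
    chemotactic mediators depressed in 4th-generation users.
    """
    gold3 = {m: 1.5 for m in _GOLD3_INFLAMMATORY}
    gold3.update({m: 1.0 for m in _PROTEASE_AXIS})
    groups = [
        GroupSpec("Control_COPD", 25),
        GroupSpec("PreCOPD", 26, {m: 1.0 for m in _PROTEASE_AXIS}),
        GroupSpec("GOLD_1_2", 29),
        GroupSpec("GOLD_3", 29, gold3),
        GroupSpec("Control_EC", 25),
        GroupSpec("EC_3rd_gen", 21, {m: 0.5 for m in ("MMP-9", "MPO", "NE")}),
        GroupSpec(
            "EC_4th_gen",
            27,
            {**{m: 0.8 for m in ("MMP-9", "MPO", "NE")}, **{m: -1.0 for m in CHEMOTACTIC}},
        ),
    ]
    batch = {
        "Control_COPD": "copd_study",
        "PreCOPD": "copd_study",
        "GOLD_1_2": "copd_study",
        "GOLD_3": "copd_study",
        "Control_EC": "ecig_study",
        "EC_3rd_gen": "ecig_study",
        "EC_4th_gen": "ecig_study",
    }
    covariates = {
        "Control_COPD": CovariateSpec(58, 9, 0.5, 28, 5, 0.05, 0.32, 0.0, 0.05),
        "PreCOPD": CovariateSpec(56, 9, 0.5, 29, 5, 0.5, 0.65, 0.15, 0.15),
        "GOLD_1_2": CovariateSpec(64, 8, 0.5, 28, 5, 0.5, 0.65, 0.2, 0.5),
        "GOLD_3": CovariateSpec(62, 8, 0.5, 27, 5, 0.45, 0.69, 0.27, 0.5),
        "Control_EC": CovariateSpec(27, 6, 0.5, 25, 4, 0.0, 0.05, 0.0, 0.0),
        "EC_3rd_gen": CovariateSpec(29, 6, 0.4, 26, 4, 0.0, 0.05, 0.0, 0.0),
        "EC_4th_gen": CovariateSpec(25, 5, 0.5, 25, 4, 0.0, 0.05, 0.0, 0.0),
    }
    return SimConfig(
        group_specs=groups,
        correlation_blocks=[
            (INFLAMMATORY, 0.6),
            (CHEMOTACTIC, 0.5),
            (PROTEASES_ENZYMES, 0.7),
        ],
        batch_assignment=batch,
        batch_additive={"ecig_study": 0.5},
        batch_multiplicative={"ecig_study": 1.2},
        lod_quantile=lod_quantile,
        noise_sd=1.0,
        covariate_model=covariates,
        seed=seed,
    )


# ---------------------------------------------------------------------- #
# Generation
# ---------------------------------------------------------------------- #


def generate_cohort(config: SimConfig) -> tuple[MediatorMatrix, pd.DataFrame, GroundTruth]:
    """Draw one synthetic cohort.

    Returns the (possibly censored) mediator matrix, the participant table,
    and the ground truth.  Identical configs (including seed) yield
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    med = list(config.mediator_names)
    m = len(med)

    if config.baseline_log2 is None:
        baseline = np.linspace(2.0, 10.0, m)
    else:
        baseline = np.array([float(config.baseline_log2[x]) for x in med])
    noise_sd = config._per_mediator(config.noise_sd, "noise_sd")
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr)

    batch_assignment = dict(config.batch_assignment) or {
        g.name: "batch1" for g in config.group_specs
    }
    add = config._per_batch_mediator(config.batch_additive, default=0.0)
    mult = config._per_batch_mediator(config.batch_multiplicative, default=1.0)

    rows, meta_rows, censor_rows = [], [], []
    truth_means = {}
    pid = 0
    for g in config.group_specs:
        batch = batch_assignment[g.name]
        shift = np.array([float(g.shifts.get(x, 0.0)) for x in med])
        truth_means[g.name] = baseline + shift

        cov = config.covariate_model.get(g.name, CovariateSpec())
        age = rng.normal(cov.age_mean, cov.age_sd, g.n)
        sex = np.where(rng.random(g.n) < cov.p_female, "female", "male")
        races = list(cov.race_probs)
        race = rng.choice(races, size=g.n, p=np.array(list(cov.race_probs.values())))
        bmi = rng.normal(cov.bmi_mean, cov.bmi_sd, g.n)
        smoker = rng.random(g.n) < cov.p_smoker
        cardio = rng.random(g.n) < cov.p_cardiovascular
        pulmvasc = rng.random(g.n) < cov.p_pulmonary_vascular
        steroid = rng.random(g.n) < cov.p_inhaled_steroid

        z = rng.standard_normal((g.n, m)) @ chol.T
        noise = z * noise_sd
        struct = baseline + shift + np.outer(age - 50.0, np.full(m, config.age_slope))
        log2vals = (
            struct
            + add.loc[batch].to_numpy()
            + mult.loc[batch].to_numpy() * noise
        )
        rows.append(log2vals)
        for i in range(g.n):
            meta_rows.append(
                {
                    "participant_id": f"P{pid:04d}",
                    "group": g.name,
                    "batch": batch,
                    "age": age[i],
                    "sex": sex[i],
                    "race": race[i],
                    "bmi": bmi[i],
                    "smoking_current": int(smoker[i]),
                    "cardiovascular": int(cardio[i]),
                    "pulmonary_vascular": int(pulmvasc[i]),
                    "inhaled_steroid": int(steroid[i]),
                }
            )
            pid += 1

    participants = pd.DataFrame(meta_rows).set_index("participant_id")
    values = pd.DataFrame(
        np.exp2(np.vstack(rows)), index=participants.index, columns=med
    )
    matrix = MediatorMatrix(values)
    matrix = censor_at_lod(matrix, config.lod_quantile)

    truth = GroundTruth(
        group_log2_means=pd.DataFrame(truth_means, index=med).T,
        batch_additive=add,
        batch_multiplicative=mult,
        correlation=corr,
        lod=matrix.lod.copy(),
        censored=matrix.mask.copy(),
    )
    return matrix, participants, truth


def censor_at_lod(matrix: MediatorMatrix, lod_quantile) -> MediatorMatrix:
    """Left-censor each mediator at the configured empirical quantile.

    The per-mediator LOD is set to the ``lod_quantile`` quantile of that
    mediator's marginal distribution; every value strictly below its LOD is
    replaced by missing.  ``lod_quantile`` may be a scalar or a per-mediator
    mapping; each value must lie in [0, 0.25].
    """
    if matrix.values.isna().any().any():
        raise ValueError("censor_at_lod requires a fully observed matrix")
    if isinstance(lod_quantile, Mapping):
        q = pd.Series(
            {m: float(lod_quantile.get(m, 0.0)) for m in matrix.mediators}, dtype=float
        )
    else:
        q = pd.Series(float(lod_quantile), index=matrix.mediators, dtype=float)
    if ((q < 0) | (q > 0.25)).any():
        raise ValueError(f"lod_quantile outside [0, 0.25]: {q[(q < 0) | (q > 0.25)].to_dict()}")

    values = matrix.values.copy()
    lod = pd.Series(
        {m: float(np.quantile(values[m].to_numpy(), q[m])) for m in matrix.mediators}
    )
    for m in matrix.mediators:
        values.loc[values[m] < lod[m], m] = np.nan
    return MediatorMatrix(values, lod, matrix.scale)
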