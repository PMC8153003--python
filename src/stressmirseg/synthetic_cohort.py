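"""Synthetic cohort generator for the stress-segregation qPCR pipeline.

Emulates the study design the downstream analysis assumes: a cohort of
male mice split into an unstressed control group and a stressed group,
with pre-trauma acoustic-startle (ASR) baselines, two post-stress ASR
sessions expressed as % of baseline, post-segregation behavioral readouts
(open field, elevated plus maze, 5-trial social memory), and triplicate
RT-qPCR Ct values for four miRNAs (miR-15a-5p, let-7d-5p, miR-511-5p,
miR-497a-5p) and two target mRNAs (FKBP5, BDNF) plus the endogenous
references (GAPDH for mRNAs, U6 for miRNAs) in up to three brain areas
(hippocampus HIP, hypothalamus HT, medial prefrontal cortex mPFC).

The generative model is Gaussian on the delta-Ct scale (log2-linear in
expression, the standard qPCR noise model). A continuous latent
susceptibility trait per stressed mouse couples the size of its ASR
change to the size of its expression shift toward the "susceptible"
profile; the trait itself is never used by the analysis — phenotype
labels are only ever assigned downstream by the arousal-score threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# study constants
# --------------------------------------------------------------------------

MIRNAS: tuple[str, ...] = ("miR-15a-5p", "let-7d-5p", "miR-511-5p", "miR-497a-5p")
MRNAS: tuple[str, ...] = ("FKBP5", "BDNF")
ANALYTES: tuple[str, ...] = MIRNAS + MRNAS
REFERENCE_ANALYTES: tuple[str, ...] = ("GAPDH", "U6")
AREAS: tuple[str, ...] = ("HIP", "HT", "mPFC")

#: endogenous reference used to form delta-Ct for each analyte
DEFAULT_REFERENCE_MAP: dict[str, str] = {
    **{m: "U6" for m in MIRNAS},
    **{m: "GAPDH" for m in MRNAS},
}

BEHAVIOR_MEASURES: tuple[str, ...] = ("of_measure", "epm_measure", "sm_measure")

BEHAVIOR_COLUMNS: tuple[str, ...] = (
    "mouse_id",
    "group",
    "areas",
    "asr_baseline",
    "asr1_pct",
    "asr2_pct",
    "of_measure",
    "epm_measure",
    "sm_measure",
    "latent_susceptibility",
)
CT_COLUMNS: tuple[str, ...] = ("mouse_id", "area", "analyte", "replicate", "ct")


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


class CohortParseError(ValueError):
    """Malformed cohort file."""


def round_sig(x: float, sig: int = 6) -> float:
    """Round to ``sig`` significant digits (the package's output precision)."""
    return float(f"{float(x):.{sig}g}")


def _round_sig_arr(a: np.ndarray, sig: int = 6) -> np.ndarray:
    return np.array([round_sig(v, sig) for v in np.ravel(a)]).reshape(np.shape(a))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ASRModel:
    """Post-stress ASR change model (% of pre-trauma baseline).

    Sessions are days 14 (ASR1) and 28 (ASR2) post stress. Controls vary
    around 100% of baseline. Stressed mice receive a mean shift plus a
    contribution from the latent susceptibility trait (percent points per
    SD of the trait), so more susceptible mice startle more.
    """

    control_mean: tuple[float, float] = (100.0, 100.0)
    control_sd: tuple[float, float] = (15.0, 15.0)
    stressed_mean: tuple[float, float] = (109.0, 109.0)
    session_sd: tuple[float, float] = (8.0, 8.0)
    susceptibility_coupling: float = 9.0
    baseline_mean: float = 520.0
    baseline_sd: float = 80.0


@dataclass(frozen=True)
class BehaviorMeasureModel:
    """One post-segregation behavioral readout (arbitrary units).

    Raw units are oriented so that lower values are more PTSD-like
    (e.g. less center time, less open-arm time, worse social memory);
    the scoring layer re-orients them.
    """

    control_mean: float = 100.0
    control_sd: float = 15.0
    stressed_shift: float = -8.0
    susceptibility_coupling: float = -6.0


@dataclass(frozen=True)
class AreaExpressionModel:
    """Per-brain-area expression model on the delta-Ct scale.

    ``shift_susceptible`` / ``shift_resilient`` are mean delta-Ct shifts
    per analyte for the two stressed phenotypes relative to controls
    (negative shift = upregulation). A stressed mouse with latent trait
    ``lam`` gets the midpoint profile plus ``lam`` times the half
    difference, so lam = +1 lands on the susceptible profile and lam = -1
    on the resilient one. ``correlation`` is the analyte-by-analyte
    correlation of the biological (between-mouse) delta-Ct noise.
    """

    analytes: tuple[str, ...] = ANALYTES
    base_ct: tuple[float, ...] = (24.0, 23.0, 26.0, 25.0, 27.0, 28.0)
    shift_susceptible: tuple[float, ...] = (0.0,) * 6
    shift_resilient: tuple[float, ...] = (0.0,) * 6
    sd: tuple[float, ...] = (1.0,) * 6
    correlation: tuple[tuple[float, ...], ...] = tuple(
        tuple(row) for row in np.eye(6)
    )

    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.correlation, dtype=float)


@dataclass(frozen=True)
class SubcohortSpec:
    """A set of mice dissected for the same brain areas."""

    areas: tuple[str, ...]
    n_control: int
    n_stressed: int


def _corr(block: float, fkbp5: Sequence[float], bdnf: Sequence[float],
          fkbp5_bdnf: float) -> tuple[tuple[float, ...], ...]:
    """Six-analyte correlation (order: 4 miRNAs, FKBP5, BDNF)."""
    c = np.eye(6)
    for i in range(4):
        for j in range(i + 1, 4):
            c[i, j] = c[j, i] = block
    for i in range(4):
        c[i, 4] = c[4, i] = fkbp5[i]
        c[i, 5] = c[5, i] = bdnf[i]
    c[4, 5] = c[5, 4] = fkbp5_bdnf
    return tuple(tuple(row) for row in c)


def default_expression_models() -> dict[str, AreaExpressionModel]:
    """Area models matching the direction of the reported group effects.

    HIP: susceptible mice show lower miR-15a/511/497a and higher
    FKBP5/BDNF than resilient ones; miRNA:FKBP5 correlations negative.
    mPFC: all-stressed miRNA downregulation regardless of phenotype,
    target upregulation in susceptible mice, near-zero miRNA:target
    correlation. HT: resilient upregulation of miR-15a/511/497a,
    let-7d up in all stressed mice, FKBP5 down / BDNF up in resilient,
    strongly negative miRNA:FKBP5 and positive miRNA:BDNF correlations.
    Shifts are on the delta-Ct scale: -1 means a 2-fold increase.
    """
    return {
        # analyte order: miR-15a-5p, let-7d-5p, miR-511-5p, miR-497a-5p, FKBP5, BDNF
        "HIP": AreaExpressionModel(
            shift_susceptible=(0.0, 0.0, 0.8, 0.8, -0.3, -0.5),
            shift_resilient=(-0.8, 0.0, 0.0, 0.0, 0.7, 0.5),
            correlation=_corr(0.45, (-0.45, -0.10, -0.45, -0.45), (0, 0, 0, 0), 0.2),
        ),
        "HT": AreaExpressionModel(
            shift_susceptible=(0.0, -0.8, 0.0, 0.3, 0.0, 0.0),
            shift_resilient=(-1.0, -0.8, -1.0, -0.7, 1.0, -1.0),
            correlation=_corr(0.60, (-0.60, -0.35, -0.60, -0.60),
                              (0.6, 0.6, 0.6, 0.6), -0.5),
        ),
        "mPFC": AreaExpressionModel(
            shift_susceptible=(1.0, 1.0, 1.0, 0.3, -1.0, -1.0),
            shift_resilient=(1.0, 1.0, 1.0, 0.3, 0.0, 0.0),
            correlation=_corr(0.40, (0, -0.15, -0.15, 0), (-0.1, -0.2, -0.3, 0), 0.1),
        ),
    }


def default_behavior_models() -> dict[str, BehaviorMeasureModel]:
    return {m: BehaviorMeasureModel() for m in BEHAVIOR_MEASURES}


@dataclass(frozen=True)
class CohortConfig:
    """Full simulation configuration.

    Defaults reproduce the study design: 30 mice (12 control / 18
    stressed) dissected for HIP and mPFC plus 16 mice (6 / 10) dissected
    for HT — 46 mice in total — with an arousal model calibrated so the
    downstream threshold segregation yields on average ~30% susceptible
    stressed mice.
    """

    subcohorts: tuple[SubcohortSpec, ...] = (
        SubcohortSpec(("HIP", "mPFC"), 12, 18),
        SubcohortSpec(("HT",), 6, 10),
    )
    seed: int = 0
    asr_model: ASRModel = field(default_factory=ASRModel)
    behavior_model: Mapping[str, BehaviorMeasureModel] = field(
        default_factory=default_behavior_models
    )
    expression_model: Mapping[str, AreaExpressionModel] = field(
        default_factory=default_expression_models
    )
    replicate_sd: float = 0.15
    susceptibility_link: float = 1.0
    reference_base_ct: Mapping[str, float] = field(
        default_factory=lambda: {"GAPDH": 18.0, "U6": 22.0}
    )
    reference_noise_sd: float = 0.1
    loading_sd: float = 0.3

    @property
    def n_control(self) -> int:
        return sum(s.n_control for s in self.subcohorts)

    @property
    def n_stressed(self) -> int:
        return sum(s.n_stressed for s in self.subcohorts)

    def validate(self) -> None:
        if self.n_control < 2 or self.n_stressed < 4:
            raise CohortConfigError(
                f"cohort too small: n_control={self.n_control} (need >= 2), "
                f"n_stressed={self.n_stressed} (need >= 4)"
            )
        if self.replicate_sd < 0:
            raise CohortConfigError("replicate_sd must be >= 0")
        for area, model in self.expression_model.items():
            c = model.correlation_matrix()
            k = len(model.analytes)
            if c.shape != (k, k):
                raise CohortConfigError(
                    f"correlation matrix for area {area!r} has shape {c.shape}, "
                    f"expected ({k}, {k})"
                )
            if not np.allclose(c, c.T):
                raise CohortConfigError(
                    f"correlation matrix for area {area!r} is not symmetric"
                )
            if not np.allclose(np.diag(c), 1.0):
                raise CohortConfigError(
                    f"correlation matrix for area {area!r} lacks a unit diagonal"
                )
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise CohortConfigError(
                    f"correlation matrix for area {area!r} is not positive "
                    "semidefinite"
                )


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Configuration with every effect size zero.

    Stressed mice are statistically indistinguishable from controls in
    both behavior and expression; useful for calibration/null checks.
    """
    kwargs = dict(
        seed=seed,
        asr_model=ASRModel(stressed_mean=(100.0, 100.0),
                           session_sd=(15.0, 15.0),
                           susceptibility_coupling=0.0),
        behavior_model={m: BehaviorMeasureModel(stressed_shift=0.0,
                                                susceptibility_coupling=0.0)
                        for m in BEHAVIOR_MEASURES},
        expression_model={a: AreaExpressionModel(correlation=m.correlation)
                          for a, m in default_expression_models().items()},
        susceptibility_link=0.0,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def null_expression_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default behavior but zero expression effects.

    Segregation proceeds as usual while expression carries no phenotype
    signal, so per-analyte ANOVA across phenotypes is a true null.
    """
    kwargs = dict(
        seed=seed,
        expression_model={a: AreaExpressionModel(correlation=m.correlation)
                          for a, m in default_expression_models().items()},
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


# --------------------------------------------------------------------------
# records
# --------------------------------------------------------------------------


@dataclass
class MouseRecord:
    """One mouse's behavioral record.

    ``latent_susceptibility`` is simulation bookkeeping only and is never
    consumed by the analysis layers.
    """

    mouse_id: str
    group: str  # {"control", "stressed"}
    areas: tuple[str, ...]
    asr_baseline: float
    asr1_pct: float
    asr2_pct: float
    of_measure: float
    epm_measure: float
    sm_measure: float
    latent_susceptibility: float


def records_to_frame(records: Iterable[MouseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["areas"] = ",".join(r.areas)
        rows.append(d)
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[MouseRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            MouseRecord(
                mouse_id=str(row.mouse_id),
                group=str(row.group),
                areas=tuple(str(row.areas).split(",")),
                asr_baseline=float(row.asr_baseline),
                asr1_pct=float(row.asr1_pct),
                asr2_pct=float(row.asr2_pct),
                of_measure=float(row.of_measure),
                epm_measure=float(row.epm_measure),
                sm_measure=float(row.sm_measure),
                latent_susceptibility=float(row.latent_susceptibility),
            )
        )
    return records


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple[list[MouseRecord], pd.DataFrame]:
    """Simulate one cohort.

    Returns the behavioral records and a long-format Ct table with one
    row per (mouse, area, analyte, replicate). Deterministic given
    ``config.seed``; all emitted numbers are rounded to 6 significant
    digits so written files round-trip exactly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    asr = config.asr_model

    records: list[MouseRecord] = []
    ct_rows: list[tuple] = []
    mouse_counter = 0

    for sub in config.subcohorts:
        groups = ["control"] * sub.n_control + ["stressed"] * sub.n_stressed
        for grp in groups:
            mouse_counter += 1
            mid = f"m{mouse_counter:03d}"
            lam = rng.normal()
            stressed = grp == "stressed"
            link = config.susceptibility_link if stressed else 0.0

            baseline = max(rng.normal(asr.baseline_mean, asr.baseline_sd), 1.0)
            pct = []
            for s in range(2):
                if stressed:
                    mu = asr.stressed_mean[s] + link * asr.susceptibility_coupling * lam
                    sd = asr.session_sd[s]
                else:
                    mu, sd = asr.control_mean[s], asr.control_sd[s]
                pct.append(max(rng.normal(mu, sd), 0.0))

            behav = {}
            for name in BEHAVIOR_MEASURES:
                m = config.behavior_model[name]
                mu = m.control_mean
                if stressed:
                    mu += m.stressed_shift + link * m.susceptibility_coupling * lam
                behav[name] = rng.normal(mu, m.control_sd)

            records.append(
                MouseRecord(
                    mouse_id=mid,
                    group=grp,
                    areas=tuple(sub.areas),
                    asr_baseline=round_sig(baseline),
                    asr1_pct=round_sig(pct[0]),
                    asr2_pct=round_sig(pct[1]),
                    of_measure=round_sig(behav["of_measure"]),
                    epm_measure=round_sig(behav["epm_measure"]),
                    sm_measure=round_sig(behav["sm_measure"]),
                    latent_susceptibility=round_sig(lam),
                )
            )

            for area in sub.areas:
                model = config.expression_model[area]
                k = len(model.analytes)
                loading = rng.normal(0.0, config.loading_sd)
                chol = np.linalg.cholesky(
                    model.correlation_matrix() + 1e-12 * np.eye(k)
                )
                noise = np.asarray(model.sd) * (chol @ rng.normal(size=k))
                shift = np.zeros(k)
                if stressed:
                    s_s = np.asarray(model.shift_susceptible)
                    s_r = np.asarray(model.shift_resilient)
                    shift = (s_s + s_r) / 2.0 + link * lam * (s_s - s_r) / 2.0
                true_ct = np.asarray(model.base_ct) + loading + shift + noise
                for analyte, ct in zip(model.analytes, true_ct):
                    for rep in (1, 2, 3):
                        val = ct + rng.normal(0.0, config.replicate_sd)
                        ct_rows.append((mid, area, analyte, rep, round_sig(val)))
                for ref, base in config.reference_base_ct.items():
                    ref_ct = base + loading + rng.normal(0.0, config.reference_noise_sd)
                    for rep in (1, 2, 3):
                        val = ref_ct + rng.normal(0.0, config.replicate_sd)
                        ct_rows.append((mid, area, ref, rep, round_sig(val)))

    ct_table = pd.DataFrame(ct_rows, columns=CT_COLUMNS)
    _validate_ct_table(ct_table)
    return records, ct_table


def _validate_ct_table(ct_table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise CohortParseError(f"Ct table missing columns: {sorted(missing)}")
    bad = ct_table[(ct_table["ct"] <= 0) | (ct_table["ct"] >= 45)]
    if len(bad):
        row = bad.iloc[0]
        raise CohortParseError(
            f"Ct value {row['ct']} out of range (0, 45) for mouse "
            f"{row['mouse_id']} {row['area']}/{row['analyte']}"
        )
    counts = ct_table.groupby(["mouse_id", "area", "analyte"], sort=False).size()
    off = counts[counts != 3]
    if len(off):
        key = off.index[0]
        raise CohortParseError(
            f"expected exactly 3 replicates, found {off.iloc[0]} for {key}"
        )
    for (mouse, area), grp in ct_table.groupby(["mouse_id", "area"], sort=False):
        analytes = set(grp["analyte"])
        if not analytes & set(REFERENCE_ANALYTES):
            raise CohortParseError(
                f"no reference analyte (GAPDH/U6) for mouse {mouse} area {area}"
            )


# --------------------------------------------------------------------------
# persistence (TSV, 6 significant digits)
# --------------------------------------------------------------------------


def write_cohort(records: Iterable[MouseRecord], ct_table: pd.DataFrame,
                 directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    behavior_path = directory / "behavior.tsv"
    ct_path = directory / "ct.tsv"
    records_to_frame(records).to_csv(
        behavior_path, sep="\t", index=False, float_format="%.6g"
    )
    ct_table.to_csv(ct_path, sep="\t", index=False, float_format="%.6g")
    return {"behavior": behavior_path, "ct": ct_path}


def _parse_float(text: str, path: Path, line_no: int, column: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise CohortParseError(
            f"{path}, line {line_no}: cannot parse {column}={text!r} as a number"
        ) from None


def read_cohort(directory: str | Path) -> tuple[list[MouseRecord], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`.

    Malformed numeric fields raise :class:`CohortParseError` with the file
    and line number rather than being dropped or coerced to NaN.
    """
    directory = Path(directory)
    behavior_path = directory / "behavior.tsv"
    ct_path = directory / "ct.tsv"

    bframe = pd.read_csv(behavior_path, sep="\t", dtype=str,
                         keep_default_na=False)
    missing = set(BEHAVIOR_COLUMNS) - set(bframe.columns)
    if missing:
        raise CohortParseError(
            f"{behavior_path}: missing columns {sorted(missing)}"
        )
    numeric_cols = [c for c in BEHAVIOR_COLUMNS if c not in
                    ("mouse_id", "group", "areas")]
    for col in numeric_cols:
        bframe[col] = [
            _parse_float(v, behavior_path, i + 2, col)
            for i, v in enumerate(bframe[col])
        ]
    records = frame_to_records(bframe)

    cframe = pd.read_csv(ct_path, sep="\t", dtype=str,
                         keep_default_na=False)
    missing = set(CT_COLUMNS) - set(cframe.columns)
    if missing:
        raise CohortParseError(f"{ct_path}: missing columns {sorted(missing)}")
    cframe["replicate"] = [
        int(_parse_float(v, ct_path, i + 2, "replicate"))
        for i, v in enumerate(cframe["replicate"])
    ]
    cframe["ct"] = [
        _parse_float(v, ct_path, i + 2, "ct") for i, v in enumerate(cframe["ct"])
    ]
    _validate_ct_table(cframe)
    return records, cframe
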