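"""End-to-end run: generate -> segregate -> quantify -> stats -> synergy ->
overlap -> enrich, with a reproducibility manifest.

A single run seed fans out to the cohort generator through a seed
sequence, every output table is written with fixed 6-significant-digit
formatting and deterministic row order, and the manifest records the
seed, a hash of the configuration and a checksum per output file, so a
rerun with the same configuration and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ais_segregation import SCORE_COLUMNS, SegregationConfig, composite_scores
from .group_stats import (correlation_matrix, one_way_anova, pearson,
                          significance_stars, tukey_hsd)
from .pathway_enrichment import enrich, read_gmt
from .regulator_overlap import (load_lncrna_sets, load_regulator_sets,
                                load_tf_sets, pairwise_overlap)
from .rq_quantification import quantify_cohort, rq_wide
from .synergy_regression import (report_frame, ledger_frame, score_regressions,
                                 search_all_targets)
from .synthetic_cohort import (AREAS, MIRNAS, MRNAS, CohortConfig,
                               generate_cohort, read_cohort, records_to_frame,
                               write_cohort)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed."""


@dataclass
class RunConfig:
    out_dir: str | Path = "stressmirseg_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segregation: SegregationConfig = field(default_factory=SegregationConfig)
    #: load an existing cohort instead of simulating one
    cohort_dir: str | Path | None = None
    areas: tuple[str, ...] = AREAS
    admissibility_mode: str = "strict"
    fdr_threshold: float = 0.05
    #: mice entering the expression correlation tables: all | stressed
    expression_correlation_population: str = "all"
    #: mice entering score correlations / score regressions
    score_population: str = "stressed"
    tf_sets_path: str | Path | None = None
    lncrna_sets_path: str | Path | None = None
    gmt_path: str | Path | None = None
    targets_path: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "segregation" in raw:
            raw["segregation"] = SegregationConfig(**raw["segregation"])
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "areas" in raw:
            raw["areas"] = tuple(raw["areas"])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, frozenset)):
            return str(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # where results land is not part of what ran
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def anova_table(rq: pd.DataFrame, areas) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (area, analyte) one-way ANOVA across phenotypes plus Tukey rows.

    Phenotype groups with fewer than 2 mice are dropped from that
    analyte's comparison (with a log notice); analytes left with fewer
    than 2 groups are skipped.
    """
    anova_rows, tukey_rows = [], []
    for area in areas:
        sub = rq[rq["area"] == area]
        for analyte in sorted(sub["analyte"].unique()):
            cell = sub[sub["analyte"] == analyte]
            groups, names = [], []
            for label in ("control", "susceptible", "resilient"):
                vals = cell.loc[cell["phenotype"] == label, "rq"].to_numpy()
                if vals.size >= 2:
                    groups.append(vals)
                    names.append(label)
                elif vals.size:
                    logger.info("%s/%s: phenotype %s has n=%d, dropped from "
                                "ANOVA", area, analyte, label, vals.size)
            if len(groups) < 2:
                logger.info("%s/%s: fewer than 2 usable groups, skipped",
                            area, analyte)
                continue
            res = one_way_anova(groups, analyte=analyte, area=area)
            anova_rows.append((area, analyte,
                               "/".join(str(n) for n in res.group_ns),
                               res.F, res.p))
            try:
                for comp in tukey_hsd(groups, names):
                    tukey_rows.append((area, analyte, comp.pair[0],
                                       comp.pair[1], comp.mean_difference,
                                       comp.q, comp.p_adjusted))
            except ValueError as exc:
                logger.info("%s/%s: Tukey skipped (%s)", area, analyte, exc)
    anova = pd.DataFrame(anova_rows,
                         columns=["area", "analyte", "group_ns", "F", "p"])
    tukey = pd.DataFrame(tukey_rows,
                         columns=["area", "analyte", "group_a", "group_b",
                                  "mean_difference", "q", "p_adjusted"])
    return anova, tukey


def target_correlation_table(rq_by_area: Mapping[str, pd.DataFrame]
                             ) -> pd.DataFrame:
    """miRNA vs target-mRNA Pearson correlations per area (RQ scale)."""
    rows = []
    for area, wide in rq_by_area.items():
        for target in MRNAS:
            for mirna in MIRNAS:
                sub = wide[[target, mirna]].dropna()
                res = pearson(sub[target], sub[mirna], target, mirna)
                rows.append((area, target, mirna, res.r, res.p, res.n,
                             significance_stars(res.p)))
    return pd.DataFrame(rows, columns=["area", "target", "mirna", "r", "p",
                                       "n", "stars"])


def mirna_correlation_table(rq_by_area: Mapping[str, pd.DataFrame]
                            ) -> pd.DataFrame:
    """miRNA:miRNA correlation matrix per area, long form."""
    rows = []
    for area, wide in rq_by_area.items():
        mat = correlation_matrix(wide, MIRNAS)
        for i in range(len(MIRNAS)):
            for j in range(i):
                a, b = MIRNAS[j], MIRNAS[i]
                rows.append((area, b, a, mat.r.loc[a, b], mat.p.loc[a, b],
                             int(mat.n.loc[a, b]), mat.formatted.loc[b, a]))
    return pd.DataFrame(rows, columns=["area", "mirna_row", "mirna_col", "r",
                                       "p", "n", "cell"])


def score_correlation_table(scores: pd.DataFrame,
                            rq_by_area: Mapping[str, pd.DataFrame],
                            population: str = "stressed") -> pd.DataFrame:
    """Expression vs behavioral-score correlations per area."""
    idx = scores.set_index("mouse_id")
    if population == "stressed":
        idx = idx[idx["phenotype"].isin(("susceptible", "resilient"))]
    rows = []
    for area, wide in rq_by_area.items():
        merged = idx.join(wide, how="inner")
        for analyte in MIRNAS + MRNAS:
            for score in SCORE_COLUMNS:
                sub = merged[[analyte, score]].dropna()
                res = pearson(sub[analyte], sub[score], analyte, score)
                rows.append((area, analyte, score, res.r, res.p, res.n,
                             significance_stars(res.p)))
    return pd.DataFrame(rows, columns=["area", "analyte", "score", "r", "p",
                                       "n", "stars"])


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Emits behavior/ct tables, scores, RQ values, ANOVA + Tukey results,
    the three correlation tables, the best-subset model report with its
    full enumeration ledger, the behavioral-score models, both regulator
    overlap matrices, the pathway enrichment table and a manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_dir is not None:
        records, ct = _stage("cohort")(read_cohort, config.cohort_dir)
    else:
        cohort_seed = int(
            np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31)
        )
        cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
        records, ct = _stage("cohort")(generate_cohort, cohort_cfg)
    write_cohort(records, ct, out)

    scores = _stage("segregation")(composite_scores, records,
                                   config.segregation)
    _write(scores, out / "scores.tsv")

    phenotypes = scores.set_index("mouse_id")["phenotype"]
    rq = _stage("quantification")(quantify_cohort, ct, phenotypes)
    _write(rq, out / "rq.tsv")

    areas = [a for a in config.areas if a in set(rq["area"])]
    rq_by_area = {a: rq_wide(rq, a) for a in areas}
    if config.expression_correlation_population == "stressed":
        stressed_ids = set(phenotypes[phenotypes != "control"].index)
        corr_by_area = {a: w.loc[w.index.isin(stressed_ids)]
                        for a, w in rq_by_area.items()}
    else:
        corr_by_area = rq_by_area

    anova, tukey = _stage("anova")(anova_table, rq, areas)
    _write(anova, out / "anova.tsv")
    _write(tukey, out / "tukey.tsv")

    _write(_stage("correlation")(target_correlation_table, corr_by_area),
           out / "corr_targets.tsv")
    _write(_stage("correlation")(mirna_correlation_table, corr_by_area),
           out / "corr_mirnas.tsv")
    _write(_stage("correlation")(score_correlation_table, scores, rq_by_area,
                                 config.score_population),
           out / "corr_scores.tsv")

    reports = _stage("synergy")(search_all_targets, corr_by_area,
                                MRNAS, MIRNAS, config.admissibility_mode)
    _write(report_frame(reports), out / "synergy_models.tsv")
    _write(ledger_frame(reports), out / "synergy_ledger.tsv")

    score_fits = _stage("score-regression")(
        score_regressions, scores, rq_by_area,
        SCORE_COLUMNS, config.score_population)
    score_frame = pd.DataFrame(
        [(f.area, *f.target.split("|"), f.R, f.R2, f.p, f.n)
         for f in score_fits],
        columns=["area", "score", "predictor_set", "R", "R2", "p", "n"])
    _write(score_frame, out / "score_models.tsv")

    tf_sets = (load_regulator_sets(config.tf_sets_path, "ChIP-derived TF")
               if config.tf_sets_path else load_tf_sets())
    lnc_sets = (load_regulator_sets(config.lncrna_sets_path, "predicted lncRNA")
                if config.lncrna_sets_path else load_lncrna_sets())
    for sets, name in ((tf_sets, "tf_overlap.tsv"),
                       (lnc_sets, "lncrna_overlap.tsv")):
        matrix = _stage("overlap")(pairwise_overlap, sets)
        frame = matrix.to_frame().reset_index(names="miRNA")
        frame.attrs["common_all"] = matrix.common_all
        _write(frame, out / name)
        (out / name.replace(".tsv", "_common.txt")).write_text(
            "\n".join(matrix.common_all) + "\n")

    from .regulator_overlap import _packaged
    gmt = config.gmt_path or _packaged("synthetic_pathways.gmt")
    targets_path = config.targets_path or _packaged("synthetic_targets.txt")
    collection = _stage("enrichment")(read_gmt, gmt)
    targets = [t.strip() for t in Path(targets_path).read_text().splitlines()
               if t.strip()]
    _write(_stage("enrichment")(enrich, targets, collection,
                                config.fdr_threshold),
           out / "enrich.tsv")

    manifest = {
        "package": "stressmirseg",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "n_mice": len(records),
        "phenotype_counts": phenotypes.value_counts().to_dict(),
        "outputs": {},
    }
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.txt")):
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
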