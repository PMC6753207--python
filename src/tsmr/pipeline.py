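"""Config-driven orchestration of the full summary-data MR analysis.

One run executes, per exposure trait: instrument selection (significance
filter, optional LD pruning, optional proxy substitution), harmonization
against the outcome table, then per-cancer and pooled (smoking-related /
non-smoking-related / all) IVW estimation, the sensitivity suite
(MR-Egger, Cochran's Q, leave-one-out, funnel data) and the Bayesian
false-discovery grid, writing TSV/JSON reports and a run log.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bfdr import DEFAULT_PRIORS, DEFAULT_W, BfdrResult, bfdr_table
from .errors import ConfigurationError, InsufficientInstrumentsError, TsmrError
from .harmonize import DroppedInstrument, HarmonizedInstrument, harmonize, write_harmonized
from .io import (
    read_instrument_table,
    read_ld_matrix,
    read_outcome_table,
    read_proxy_table,
)
from .mr import GROUPINGS, MrResult, group_instruments, pool_groups, wald_ratio
from .report import forest_frame, results_frame, sensitivity_frame
from .select import P_GENOME_WIDE, R2_PROXY, R2_PRUNE, SelectionReport, select_instruments
from .sensitivity import EggerResult, egger_regression, funnel_data, leave_one_out
from .simulate import DEFAULT_SEED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureSpec:
    path: str
    cancer_type: str
    smoking_related: bool


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    exposures: list[ExposureSpec]
    outcome_path: str
    output_dir: str
    ld_path: str | None = None
    proxy_path: str | None = None
    p_threshold: float = P_GENOME_WIDE
    r2_prune: float = R2_PRUNE
    r2_proxy: float = R2_PROXY
    priors: tuple[float, ...] = DEFAULT_PRIORS
    bfdr_method: str = "fprp"
    prior_variance_w: float = DEFAULT_W
    drop_palindromic: bool = False
    dedupe: bool = False
    groupings: tuple[str, ...] = GROUPINGS
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("p_threshold", "r2_prune", "r2_proxy"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {value}")
        if not self.exposures:
            raise ConfigurationError("at least one exposure table is required")
        self.groupings = tuple(self.groupings)
        unknown = set(self.groupings) - set(GROUPINGS)
        if unknown:
            raise ConfigurationError(f"unknown groupings: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        exposures = [
            ExposureSpec(
                path=e["path"],
                cancer_type=e["cancer_type"],
                smoking_related=bool(e.get("smoking_related", False)),
            )
            for e in raw.pop("exposures")
        ]
        if "priors" in raw:
            raw["priors"] = tuple(raw["priors"])
        if "groupings" in raw:
            raw["groupings"] = tuple(raw["groupings"])
        return cls(exposures=exposures, **raw)

    def validate_paths(self) -> None:
        paths = [e.path for e in self.exposures] + [self.outcome_path]
        paths += [p for p in (self.ld_path, self.proxy_path) if p]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"input files not found: {missing}")


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    harmonized: list[HarmonizedInstrument]
    dropped: list[DroppedInstrument]
    selection: SelectionReport
    results: list[MrResult]
    egger: dict[str, EggerResult]
    bfdr: list[BfdrResult]
    diagnostics: list[str] = field(default_factory=list)


class _Stage:
    """Context manager attributing any failure to a named pipeline stage."""

    def __init__(self, name: str, diagnostics: list[str]):
        self.name = name
        self.diagnostics = diagnostics

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, TsmrError):
            raise TsmrError(f"stage {self.name!r}: {exc}") from exc
        return False


def run_pipeline(config: AnalysisConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Deterministic for fixed inputs: rerunning with the same config and
    files produces byte-identical reports. Partial outputs are retained
    on failure, alongside a FAILED marker naming the stage.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    diagnostics: list[str] = []
    try:
        result = _run(config, outdir, diagnostics, write_outputs)
    except Exception as exc:
        if write_outputs:
            (outdir / "FAILED").write_text(f"{exc}\n")
        raise
    if write_outputs:
        _write_log(config, result, outdir)
    return result


def _run(
    config: AnalysisConfig, outdir: Path, diagnostics: list[str], write_outputs: bool
) -> PipelineResult:
    with _Stage("read outcome", diagnostics):
        outcome = read_outcome_table(config.outcome_path)
    outcome_rsids = set(outcome)

    ld = proxies = None
    if config.ld_path:
        with _Stage("read LD matrix", diagnostics):
            ld = read_ld_matrix(config.ld_path)
    if config.proxy_path:
        with _Stage("read proxy table", diagnostics):
            proxies = read_proxy_table(config.proxy_path)

    harmonized: list[HarmonizedInstrument] = []
    dropped: list[DroppedInstrument] = []
    selection = SelectionReport()
    for spec in config.exposures:
        with _Stage(f"select instruments: {spec.cancer_type}", diagnostics):
            table = read_instrument_table(spec.path, spec.cancer_type, spec.smoking_related)
            selected, rep = select_instruments(
                table,
                outcome_rsids=outcome_rsids,
                ld=ld,
                proxies=proxies,
                p_threshold=config.p_threshold,
                r2_prune=config.r2_prune,
                r2_proxy=config.r2_proxy,
            )
            selection = selection.merge(rep)
        with _Stage(f"harmonize: {spec.cancer_type}", diagnostics):
            harm, drop = harmonize(
                selected,
                outcome,
                drop_palindromic=config.drop_palindromic,
                proxied_rsids=set(rep.proxied.values()),
            )
            harmonized.extend(harm)
            dropped.extend(drop)

    if not harmonized:
        diagnostics.append(
            "no instruments survived selection and harmonization; "
            "no MR results produced (check outcome overlap and thresholds)"
        )
        result = PipelineResult(
            harmonized=[], dropped=dropped, selection=selection,
            results=[], egger={}, bfdr=[], diagnostics=diagnostics,
        )
        if write_outputs:
            _write_tables(config, result, outdir)
        return result

    results: list[MrResult] = []
    with _Stage("IVW estimation", diagnostics):
        for grouping in config.groupings:
            results.extend(pool_groups(harmonized, grouping, dedupe=config.dedupe))
        for key, members in group_instruments(harmonized, "per-cancer").items():
            if len(members) < 2:
                ratio = wald_ratio(members[0])
                diagnostics.append(
                    f"{key}: single instrument ({members[0].rsid}); no pooled "
                    f"analysis conducted (Wald ratio {ratio.theta:.4f}); the "
                    "instrument still contributes to the pooled groups"
                )

    egger: dict[str, EggerResult] = {}
    loo_rows = []
    funnel_rows = []
    with _Stage("sensitivity analyses", diagnostics):
        group_members = {
            r.group: m
            for grouping in config.groupings
            for r, m in _results_with_members(harmonized, grouping, config.dedupe)
        }
        for res in results:
            members = group_members[res.group]
            if len(members) < 3:
                diagnostics.append(
                    f"{res.group}: fewer than 3 instruments; Egger and "
                    "leave-one-out skipped"
                )
                continue
            egger[res.group] = egger_regression(members)
            for loo in leave_one_out(members):
                loo_rows.append({"group": res.group, **dataclasses.asdict(loo)})
            fd = funnel_data([wald_ratio(h) for h in members], res.theta_ivw)
            fd.insert(0, "group", res.group)
            funnel_rows.append(fd)

    with _Stage("BFDR", diagnostics):
        bfdr = bfdr_table(
            results,
            priors=config.priors,
            method=config.bfdr_method,
            prior_variance_w=config.prior_variance_w,
        )

    result = PipelineResult(
        harmonized=harmonized,
        dropped=dropped,
        selection=selection,
        results=results,
        egger=egger,
        bfdr=bfdr,
        diagnostics=diagnostics,
    )
    if write_outputs:
        _write_tables(config, result, outdir, loo_rows, funnel_rows)
    return result


def _results_with_members(harmonized, grouping, dedupe):
    groups = group_instruments(harmonized, grouping)
    out = []
    for key, members in groups.items():
        if dedupe:
            seen: set[str] = set()
            members = [h for h in members if not (h.rsid in seen or seen.add(h.rsid))]
        if len(members) >= 2:
            out.append((pool_groups(members, grouping)[0], members))
    return out


def _write_tables(config, result: PipelineResult, outdir: Path, loo_rows=None, funnel_rows=None):
    import pandas as pd

    results_frame(result.results, result.bfdr).to_csv(
        outdir / "results.tsv", sep="\t", index=False
    )
    sensitivity_frame(result.egger, result.results).to_csv(
        outdir / "sensitivity.tsv", sep="\t", index=False
    )
    forest_frame(result.results).to_csv(outdir / "forest.tsv", sep="\t", index=False)
    (outdir / "selection_report.json").write_text(result.selection.to_json(indent=2) + "\n")
    write_harmonized(result.harmonized, outdir / "harmonized.tsv")
    pd.DataFrame(
        loo_rows or [],
        columns=["group", "omitted_rsid", "theta_ivw_without", "se_without", "odds_ratio_without"],
    ).to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    if funnel_rows:
        pd.concat(funnel_rows, ignore_index=True).to_csv(
            outdir / "funnel.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=["group", "rsid", "theta", "inverse_se", "theta_ivw"]).to_csv(
            outdir / "funnel.tsv", sep="\t", index=False
        )
    if (outdir / "FAILED").exists():
        (outdir / "FAILED").unlink()


def _write_log(config: AnalysisConfig, result: PipelineResult, outdir: Path) -> None:
    lines = [
        f"tsmr {__version__} | python {sys.version.split()[0]}",
        f"run at {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"seed: {config.seed}",
        f"thresholds: p<{config.p_threshold}, r2_prune={config.r2_prune}, "
        f"r2_proxy>{config.r2_proxy}",
        f"bfdr: method={config.bfdr_method}, priors={list(config.priors)}",
        f"palindromic policy: {'drop' if config.drop_palindromic else 'retain with flag'}",
        f"instruments harmonized: {len(result.harmonized)}; dropped: {len(result.dropped)}",
        f"groups analysed: {len(result.results)}",
    ]
    lines += [f"diagnostic: {d}" for d in result.diagnostics]
    lines += [f"dropped {d.rsid}: {d.reason}" for d in result.dropped]
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
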