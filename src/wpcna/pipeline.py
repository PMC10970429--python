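"""End-to-end orchestration of the co-expression analysis.

Stages run in order: behavior (entry logs -> learning outcomes) ->
standard peptide screening -> soft threshold + network -> module
detection -> eigenpeptides/membership -> trait statistics -> ROC
prediction -> individual-level candidates -> five-contrast integrative
prioritization -> TOM edge export.  Every output is a labelled DataFrame;
:func:`run_pipeline` optionally persists them as TSV/CSV next to a JSON
run manifest recording the configuration, row counts per stage and any
warnings raised.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import candidates as cand
from . import io as wio
from . import modules as mod
from . import network as net
from . import prediction as pred
from . import traits as tr

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "reproduce_reported_prediction"]


@dataclass
class PipelineConfig:
    """Tunable parameters of one full run (defaults match the target design)."""

    beta: int | None = 8
    beta_grid: tuple[int, ...] = tuple(range(1, 21))
    r2_threshold: float = 0.8
    screening_threshold: float = 0.5
    linkage_method: str = "average"
    cut_method: str = "hybrid"  # static | dynamic | hybrid
    cut_height: float | None = None
    min_module_size: int = 20
    deep_split: int = 2
    positive_threshold: int = 4
    ns_alpha: float = 0.5
    ns_top_k: int = 30
    contrasts: tuple[tuple[str, str], ...] = cand.DEFAULT_CONTRASTS
    candidate_top_n: int = 10
    rank_top_k: int = 40
    edge_threshold: float = 0.5
    n_candidate_modules: int = 2
    seed: int = 0


@dataclass
class PipelineResult:
    outcomes: pd.DataFrame
    screening: pd.DataFrame
    beta: int
    soft_threshold_table: pd.DataFrame | None
    assignment: pd.Series
    eigenpeptides: pd.DataFrame
    variance_explained: pd.Series
    membership: pd.DataFrame
    module_significance: pd.Series
    network_screening: pd.DataFrame
    roc: pd.DataFrame
    focal_animal: str | None
    candidates: pd.DataFrame | None
    rank_table: pd.DataFrame | None
    edges: pd.DataFrame
    tom: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv().encode()
    ).hexdigest()[:16]


class _Halt(Exception):
    """Internal: carries a partial result out of a gracefully halted run."""

    def __init__(self, result: "PipelineResult"):
        self.result = result


def run_pipeline(
    intensities: pd.DataFrame,
    metadata: pd.DataFrame,
    entry_logs: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on an intensity matrix + metadata + entry logs.

    Raises RuntimeError naming the failing stage; halts gracefully (with
    a warning) when screening retains no peptides.
    """
    try:
        return _run(intensities, metadata, entry_logs, config, out_dir)
    except _Halt as h:
        warnings.warn(
            f"pipeline halted at stage {h.result.manifest['halted']!r}: "
            "screening retained no peptides",
            stacklevel=2,
        )
        return h.result


def _run(
    intensities: pd.DataFrame,
    metadata: pd.DataFrame,
    entry_logs: pd.DataFrame,
    config: PipelineConfig | None,
    out_dir: str | Path | None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    caught: list[str] = []
    manifest: dict = {"config": asdict(cfg), "stages": {}, "warnings": caught}

    def stage(name):
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # --- behavior ---------------------------------------------------
        try:
            outcomes = bh.outcomes_from_entry_logs(entry_logs)
            _, outlier_flags = bh.cluster_animals(outcomes)
        except Exception as e:
            raise RuntimeError(f"stage 'behavior' failed: {e}") from e
        stage("behavior")["n_animals"] = len(outcomes)

        # --- screening --------------------------------------------------
        try:
            X0, drop_log = net.drop_unusable_peptides(intensities)
            y = outcomes["index"]
            X, screening = tr.standard_peptide_screening(
                X0, y, cfg.screening_threshold
            )
        except Exception as e:
            raise RuntimeError(f"stage 'screening' failed: {e}") from e
        s = stage("screening")
        s["peptides_in"] = len(intensities)
        s["dropped_unusable"] = len(drop_log)
        s["retained"] = len(X)
        if X.empty:
            manifest["halted"] = "screening"
            caught.extend(str(w.message) for w in wlist)
            raise _Halt(PipelineResult(
                outcomes, screening, 0, None, pd.Series(dtype=object),
                pd.DataFrame(), pd.Series(dtype=float), pd.DataFrame(),
                pd.Series(dtype=float), pd.DataFrame(), pd.DataFrame(),
                None, None, None, pd.DataFrame(), pd.DataFrame(), manifest,
            ))

        # --- network ----------------------------------------------------
        try:
            if cfg.beta is not None:
                beta, fit_table = int(cfg.beta), None
            else:
                beta, fit_table = net.pick_soft_threshold(
                    X, list(cfg.beta_grid), cfg.r2_threshold
                )
            S = net.similarity_matrix(X)
            A = net.adjacency(S, beta)
            TOM = net.tom_similarity(A)
            D = net.tom_dissimilarity(TOM)
        except Exception as e:
            raise RuntimeError(f"stage 'network' failed: {e}") from e
        stage("network")["beta"] = beta

        # --- modules ----------------------------------------------------
        try:
            tree, ids = mod.peptide_tree(D, cfg.linkage_method)
            max_h = float(tree[:, 2].max())
            if cfg.cut_method == "static":
                height = cfg.cut_height if cfg.cut_height is not None else 0.99 * max_h
                assignment = mod.cut_static(tree, ids, height, cfg.min_module_size)
            elif cfg.cut_method == "dynamic":
                assignment = mod.cut_dynamic_tree(
                    tree, ids, cfg.min_module_size, cfg.deep_split, cfg.cut_height
                )
            elif cfg.cut_method == "hybrid":
                assignment = mod.cut_dynamic_hybrid(
                    tree, ids, D, cfg.min_module_size, cfg.deep_split,
                    cut_height=cfg.cut_height,
                )
            else:
                raise ValueError(f"unknown cut_method {cfg.cut_method!r}")
            ME, varexp = mod.module_eigenpeptides(X, assignment)
            kME = mod.module_membership(X, ME)
        except Exception as e:
            raise RuntimeError(f"stage 'modules' failed: {e}") from e
        ms = stage("modules")
        ms["n_modules"] = int((assignment.unique() != mod.GREY).sum())
        ms["n_grey"] = int((assignment == mod.GREY).sum())

        # --- trait statistics --------------------------------------------
        try:
            screened_table = screening.loc[screening["passed"].fillna(False)]
            modsig = tr.module_significance(screened_table, assignment)
            ns_table = tr.network_screening(
                X, y, ME, assignment, kME, cfg.ns_alpha, cfg.ns_top_k
            )
        except Exception as e:
            raise RuntimeError(f"stage 'trait_stats' failed: {e}") from e

        # --- prediction ---------------------------------------------------
        try:
            if len(ME):
                roc = pred.predict_learning(ME, outcomes, cfg.positive_threshold)
            else:
                roc = pd.DataFrame()
        except Exception as e:
            raise RuntimeError(f"stage 'prediction' failed: {e}") from e

        # --- candidates ---------------------------------------------------
        focal = None
        cand_table = None
        rank_table = None
        try:
            if outlier_flags.any():
                focal = str(outlier_flags.index[outlier_flags][0])
            else:
                focal = str(outcomes["index"].idxmin())
            top_modules = list(modsig.index[: cfg.n_candidate_modules])
            if top_modules and focal in X.columns:
                cd = cand.cumulative_distance_table(X, metadata, focal)
                cand_table = cand.rank_candidate_peptides(
                    cd, assignment, top_modules, cfg.candidate_top_n
                )
                subset = assignment.index[assignment.isin(top_modules)]
                de_tables = {
                    f"{a}_vs_{b}": cand.group_de(X, metadata, (a, b))
                    for a, b in cfg.contrasts
                }
                rank_table = cand.integrative_rank(
                    de_tables, subset, cfg.rank_top_k,
                    require_five=(len(cfg.contrasts) == 5),
                )
            edges = cand.export_tom_edges(TOM, assignment, cfg.edge_threshold)
        except Exception as e:
            raise RuntimeError(f"stage 'candidates' failed: {e}") from e
        stage("candidates")["focal_animal"] = focal
        stage("edges")["n_edges"] = len(edges)

        caught.extend(str(w.message) for w in wlist)

    manifest["checksums"] = {
        "assignment": hashlib.sha256(
            assignment.to_csv().encode()
        ).hexdigest()[:16],
        "eigenpeptides": _checksum(ME),
    }

    result = PipelineResult(
        outcomes=outcomes,
        screening=screening,
        beta=beta,
        soft_threshold_table=fit_table,
        assignment=assignment,
        eigenpeptides=ME,
        variance_explained=varexp,
        membership=kME,
        module_significance=modsig,
        network_screening=ns_table,
        roc=roc,
        focal_animal=focal,
        candidates=cand_table,
        rank_table=rank_table,
        edges=edges,
        tom=TOM,
        manifest=manifest,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.outcomes.to_csv(out_dir / "outcomes.csv")
    result.screening.to_csv(out_dir / "screening.tsv", sep="\t")
    result.assignment.rename("module").to_csv(
        out_dir / "module_assignment.tsv", sep="\t"
    )
    result.eigenpeptides.to_csv(out_dir / "eigenpeptides.tsv", sep="\t")
    result.membership.to_csv(out_dir / "kme.tsv", sep="\t")
    result.module_significance.to_csv(out_dir / "module_significance.tsv", sep="\t")
    result.network_screening.to_csv(out_dir / "network_screening.tsv", sep="\t")
    result.roc.to_csv(out_dir / "roc.tsv", sep="\t")
    if result.candidates is not None:
        result.candidates.to_csv(out_dir / "candidates.tsv", sep="\t")
    if result.rank_table is not None:
        result.rank_table.to_csv(out_dir / "integrative_rank.tsv", sep="\t")
    result.edges.to_csv(out_dir / "tom_edges.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def reproduce_reported_prediction(
    eigenpeptide_path: str | Path,
    cogwall_path: str | Path,
    modules: tuple[str, ...] = ("turquoise", "black"),
    positive_threshold: int = 4,
) -> pd.DataFrame:
    """ROC analysis from externally supplied eigenpeptide + entry-log files.

    ``eigenpeptide_path`` is a module x animal table (TSV/CSV, first
    column module label); ``cogwall_path`` is an entry-log CSV with
    columns animal_id, day, CE, IE, TE.  Intended for re-analysis of
    published per-animal eigenpeptide tables.
    """
    ep = Path(eigenpeptide_path)
    sep = "," if ep.suffix.lower() == ".csv" else "\t"
    ME = pd.read_csv(ep, sep=sep, index_col=0)
    logs = wio.read_entry_logs(cogwall_path)
    outcomes = bh.outcomes_from_entry_logs(logs)
    roc = pred.predict_learning(
        ME.loc[list(modules)], outcomes, positive_threshold
    )
    return roc
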