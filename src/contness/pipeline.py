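"""End-to-end orchestration: aggregate -> fit -> call -> classify.

A single :class:`RunConfig` (TOML, see ``RunConfig.from_toml``) drives the
full analysis of one screen:

1. site-level counts are aggregated to per-gene total and unique matrices;
2. genes essential in the control (mean total count < 1) or conditionally
   essential in some condition are set aside — with no insertions to model,
   the count criterion already answers the question for them;
3. the remaining genes are fit with the ridge-penalized nested NB model,
   independently for the total and the unique counts, with one shared
   penalty per flavor chosen by mean BIC;
4. every non-intercept coefficient gets empirical-null local-fdr calls per
   flavor, intersected into a final direction;
5. the decision tree assigns one category per gene and condition.

Outputs: ``counts_total.tsv``, ``counts_unique.tsv``, ``fits.tsv``,
``calls.tsv``, ``tallies.tsv`` and a run manifest (JSON + TSV mirror).
Re-running an identical config reproduces byte-identical calls.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import counts_io as cio
from . import discovery as dv
from . import model_core as mc
from .errors import (
    ConfigError,
    ContnessError,
    DegenerateDistributionError,
    TooFewValuesError,
)

log = logging.getLogger("contness")

__all__ = ["RunConfig", "RunResult", "run_end_to_end"]


@dataclass
class RunConfig:
    """Inputs and tuning knobs of one end-to-end run."""

    poolcount: Path
    genes: Path
    samples: Path
    control: tuple[str, str]
    outdir: Path
    gene_dialect: str = "auto"  # auto | tsv | gff3
    trim_frac: float = 0.0
    lambda_policy: str | float = "bic-global"
    lfdr_threshold: float = 0.2
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        try:
            control = raw["control"]
            if isinstance(control, str):
                control = tuple(control.split(":", 1))
            cfg = cls(
                poolcount=Path(raw["poolcount"]),
                genes=Path(raw["genes"]),
                samples=Path(raw["samples"]),
                control=(control[0], control[1]),
                outdir=Path(raw["outdir"]),
                gene_dialect=raw.get("gene_dialect", "auto"),
                trim_frac=float(raw.get("trim_frac", 0.0)),
                lambda_policy=raw.get("lambda_policy", "bic-global"),
                lfdr_threshold=float(raw.get("lfdr_threshold", 0.2)),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"run config is missing required key {exc}") from exc
        return cfg

    def validate(self) -> None:
        for name in ("poolcount", "genes", "samples"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")


@dataclass
class RunResult:
    """Everything an end-to-end run produced."""

    counts_total: cio.GeneCountMatrix
    counts_unique: cio.GeneCountMatrix
    fits: mc.CoefficientTable
    calls: pd.DataFrame
    tallies: pd.DataFrame
    manifest: dict
    outdir: Path = field(default=Path("."))


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"].append({"stage": name, "seconds": round(dt, 3)})
            if exc is not None:
                raise ContnessError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _label_condition(label: tuple[str, str, str], control: tuple[str, str]):
    """Map a design-column label to the (background, environment) it tests."""
    kind, g, e = label
    if kind == "background":
        return (g, control[1])
    if kind == "nested":
        return (g, e)
    return None


def run_end_to_end(config: RunConfig) -> RunResult:
    """Run the full pipeline; see the module docstring for the stages."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "contness_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "control": list(config.control),
        "trim_frac": config.trim_frac,
        "lambda_policy": str(config.lambda_policy),
        "lfdr_threshold": config.lfdr_threshold,
        "stages": [],
    }

    with _stage("read-inputs", manifest):
        samples = cio.read_sample_table(config.samples)
        if not any(
            s.background == config.control[0] and s.environment == config.control[1]
            for s in samples
        ):
            raise ConfigError(
                f"control pair {config.control!r} not present in sample metadata"
            )
        dialect = config.gene_dialect
        if dialect == "auto":
            dialect = "gff3" if str(config.genes).endswith((".gff", ".gff3")) else "tsv"
        genes = cio.read_gene_table(config.genes, dialect=dialect)
        sites = cio.read_poolcount(config.poolcount, samples)

    with _stage("aggregate", manifest):
        counts_total, counts_unique = cio.aggregate_counts(
            sites, genes, trim_frac=config.trim_frac
        )
        cio.write_gene_counts(counts_total, outdir / "counts_total.tsv")
        cio.write_gene_counts(counts_unique, outdir / "counts_unique.tsv")
        manifest["n_genes"] = len(genes)
        manifest["n_samples"] = len(samples)

    with _stage("essentiality-screen", manifest):
        conditions = sorted(
            {(s.background, s.environment) for s in samples} - {config.control}
        )
        ctrl_mean = dv.condition_means(counts_total, samples, config.control)
        essential = ctrl_mean < 1
        cond_ess: dict = {}
        for cond in conditions:
            m = dv.condition_means(counts_total, samples, cond)
            cond_ess[cond] = ~essential & (m < 1)
        modeled = ~essential
        for flags in cond_ess.values():
            modeled &= ~flags
        manifest["n_essential"] = int(essential.sum())
        manifest["n_modeled"] = int(modeled.sum())

    with _stage("fit", manifest):
        X = mc.build_design(samples, config.control)
        tables = {}
        for counts in (counts_total, counts_unique):
            sub = cio.GeneCountMatrix(
                flavor=counts.flavor, values=counts.values.loc[modeled]
            )
            tables[counts.flavor] = mc.fit_all_genes(
                sub, X, lam=config.lambda_policy
            )
        fits = mc.CoefficientTable(tables=tables)
        pd.concat(
            [tables["total"].to_frame(), tables["unique"].to_frame()]
        ).to_csv(outdir / "fits.tsv", sep="\t", index=False)

    with _stage("call-and-classify", manifest):
        all_genes = counts_total.gene_ids
        records = []
        tally_rows = []
        for label in X.labels:
            cond = _label_condition(label, config.control)
            if cond is None:
                continue
            name = mc.NestedModelMatrix(
                matrix=X.matrix, labels=[label], sample_ids=X.sample_ids, control=X.control
            ).column_names()[0]
            try:
                calls_df = dv.call_condition(
                    tables["total"], tables["unique"], name, config.lfdr_threshold
                )
            except (TooFewValuesError, DegenerateDistributionError):
                # not enough converged genes to form an empirical null for
                # this coefficient: no model-based calls, categories only
                calls_df = None
            directions = pd.Series("none", index=all_genes, dtype=object)
            if calls_df is not None:
                directions.loc[calls_df.index] = calls_df["direction"]
            cls = dv.classify_genes(
                counts_total, counts_unique, samples, cond, config.control, directions
            )
            unresolved = pd.Series(False, index=all_genes)
            for flavor in ("total", "unique"):
                t = tables[flavor]
                bad = t.converged.index[~t.converged]
                unresolved.loc[bad] = True
            unresolved &= modeled.reindex(all_genes).fillna(False)

            cat = cls["category"].copy()
            cat[unresolved] = "unresolved"
            base = pd.DataFrame(
                {
                    "gene": all_genes,
                    "condition": f"{cond[0]}:{cond[1]}",
                    "coefficient": name,
                },
            )
            for col in ("beta_total", "lfdr_total", "beta_unique", "lfdr_unique"):
                if calls_df is not None:
                    base[col] = calls_df[col].reindex(all_genes).to_numpy()
                elif col.startswith("beta_"):
                    flavor = col.split("_", 1)[1]
                    base[col] = (
                        tables[flavor].beta[name].reindex(all_genes).to_numpy()
                    )
                else:
                    base[col] = np.nan
            for col in ("call_total", "call_unique"):
                base[col] = (
                    calls_df[col].reindex(all_genes).fillna("none").to_numpy()
                    if calls_df is not None
                    else "none"
                )
            base["direction"] = directions.to_numpy()
            base["category"] = cat.to_numpy()
            records.append(base)

            inter_ben = ((directions == "beneficial") & ~unresolved).sum()
            inter_det = ((directions == "detrimental") & ~unresolved).sum()
            tally_rows.append(
                {
                    "condition": f"{cond[0]}:{cond[1]}",
                    "n_essential": int(cls["essential_total"].sum()),
                    "n_cond_essential_total": int(cls["cond_essential_total"].sum()),
                    "n_cond_essential_unique": int(cls["cond_essential_unique"].sum()),
                    "n_cond_essential_overlap": int(
                        (cls["cond_essential_total"] & cls["cond_essential_unique"]).sum()
                    ),
                    "n_beneficial_total": int((base["call_total"] == "beneficial").sum()),
                    "n_beneficial_unique": int((base["call_unique"] == "beneficial").sum()),
                    "n_beneficial_overlap": int(inter_ben),
                    "n_detrimental_total": int((base["call_total"] == "detrimental").sum()),
                    "n_detrimental_unique": int((base["call_unique"] == "detrimental").sum()),
                    "n_detrimental_overlap": int(inter_det),
                    "n_unresolved": int(unresolved.sum()),
                }
            )
        calls = pd.concat(records, ignore_index=True)
        tallies = pd.DataFrame(tally_rows)
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False, float_format="%.6g")
        tallies.to_csv(outdir / "tallies.tsv", sep="\t", index=False)

    with _stage("manifest", manifest):
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        flat = {
            k: v for k, v in manifest.items() if not isinstance(v, (list, dict))
        }
        pd.DataFrame([flat]).T.reset_index().rename(
            columns={"index": "key", 0: "value"}
        ).to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    return RunResult(
        counts_total=counts_total,
        counts_unique=counts_unique,
        fits=fits,
        calls=calls,
        tallies=tallies,
        manifest=manifest,
        outdir=outdir,
    )
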