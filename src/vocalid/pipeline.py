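"""End-to-end orchestration: generate/ingest -> filter -> classify + PIC +
dissimilarity, with a consolidated CSV/JSON report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import CONTEXT_LABELS, FEATURE_COLUMNS, METADATA_COLUMNS, __version__
from .dissimilarity import (
    assign_age_class,
    daily_median_profiles,
    dissimilarity_trend,
    dyadic_dissimilarity,
)
from .identity import PIC_CONTEXTS, bonferroni_threshold, pic_by_age_class
from .pdfa import PDFAConfig, run_pdfa
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "apply_filters", "run_pipeline", "load_call_table"]

_FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``mode`` selects the input source: "synthetic" (built-in generator),
    or "features" (pre-extracted call table CSV).
    """

    mode: str = "synthetic"
    features_csv: str | None = None
    excluded_contexts: tuple[str, ...] = ("fed",)
    out_dir: str = "vocalid_out"
    seed: int = 0
    generator: GeneratorConfig | None = None
    n_permutations: int = 200
    n_selections: int = 20
    pic_contexts: tuple[str, ...] = tuple(PIC_CONTEXTS)
    dissim_standardize: bool = False
    dissim_score: str = "distance"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def apply_filters(
    calls: pd.DataFrame, excluded_contexts=("fed",)
) -> tuple[pd.DataFrame, dict]:
    """Drop calls in excluded behavioural contexts.

    Returns the filtered table and a per-context before/after count log.
    Unknown labels in the exclusion list are an error (likely a typo).
    """
    present = set(calls["context"].unique())
    unknown = [c for c in excluded_contexts if c not in present and c not in CONTEXT_LABELS]
    if unknown:
        raise ValueError(f"unknown context label(s) in exclusion list: {unknown}")
    before = calls["context"].value_counts().to_dict()
    kept = calls[~calls["context"].isin(excluded_contexts)].reset_index(drop=True)
    after = kept["context"].value_counts().to_dict()
    log = {
        "excluded_contexts": list(excluded_contexts),
        "n_before": int(len(calls)),
        "n_after": int(len(kept)),
        "per_context_before": {k: int(v) for k, v in sorted(before.items())},
        "per_context_after": {k: int(v) for k, v in sorted(after.items())},
    }
    logger.info("filtered %d -> %d calls (excluded %s)", len(calls), len(kept), list(excluded_contexts))
    return kept, log


def load_call_table(path) -> pd.DataFrame:
    """Read a call-feature CSV and validate the expected schema."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table {path} lacks columns: {missing}")
    return df


def check_partition_conservation(per_class_counts, total: int) -> bool:
    """True iff the per-stratum counts sum exactly to the pooled total."""
    return int(np.sum(np.asarray(per_class_counts, dtype=np.int64))) == int(total)


def _config_hash(cfg: PipelineConfig) -> str:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(cfg), default=_default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Outputs: pdfa.csv (one row per age-class model + pooled), pic.csv
    (parameter x age class PIC with age trends, pooled and per context),
    dissimilarity_records.csv, dissimilarity_trends.csv,
    context_composition.csv (individual x age class x context counts), and
    manifest.json. Deterministic given ``config.seed``; partial outputs are
    removed on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    if config.mode == "synthetic":
        gen = config.generator or GeneratorConfig(seed=config.seed)
        calls = generate_dataset(gen)
    elif config.mode == "features":
        if not config.features_csv:
            raise ValueError("mode='features' requires features_csv")
        calls = load_call_table(config.features_csv)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")

    calls, filter_log = apply_filters(calls, config.excluded_contexts)
    calls = calls.copy()
    calls["age_class"] = calls["age_days"].map(assign_age_class)
    age_classes = sorted(calls["age_class"].unique())

    def _write(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FORMAT)
        written.append(p)
        return p

    # --- classification: one model per age class + one pooled ---
    pdfa_rows = []
    for label, sub in [(ac, calls[calls["age_class"] == ac]) for ac in age_classes] + [
        ("pooled", calls)
    ]:
        cfg = PDFAConfig(
            n_permutations=config.n_permutations,
            n_selections=config.n_selections,
            seed=config.seed,
        )
        res = run_pdfa(sub, cfg)
        pdfa_rows.append({"model": label, **res.to_dict()})
    pdfa_df = pd.DataFrame(pdfa_rows)
    pdfa_path = _write("pdfa.csv", pdfa_df)

    # --- per-parameter identity coding ---
    pic_df = pic_by_age_class(calls, contexts=list(config.pic_contexts))
    pic_thr = bonferroni_threshold(config.alpha, len(FEATURE_COLUMNS))
    pic_df["bonferroni_m"] = pic_thr.m
    pic_df["bonferroni_threshold"] = pic_thr.rounded
    pic_df["trend_significant"] = pic_df["trend_p"] < pic_thr.raw
    pic_path = _write("pic.csv", pic_df)

    # --- dyadic dissimilarity ---
    pooled_profiles = daily_median_profiles(calls, by_context=False)
    ctx_profiles = daily_median_profiles(calls, by_context=True)
    rec_pooled = dyadic_dissimilarity(
        pooled_profiles, standardize=config.dissim_standardize, score=config.dissim_score
    )
    rec_ctx = dyadic_dissimilarity(
        ctx_profiles, standardize=config.dissim_standardize, score=config.dissim_score
    )
    records = pd.concat([rec_pooled, rec_ctx], ignore_index=True)
    rec_path = _write("dissimilarity_records.csv", records)

    contexts_present = ["pooled"] + sorted(c for c in rec_ctx["context"].unique())
    dissim_m = len(contexts_present) - 1 + 1  # per-context tests + pooled
    trend_rows = []
    for ctx in contexts_present:
        tr = dissimilarity_trend(
            records, context=ctx, alpha=config.alpha, bonferroni_m=dissim_m
        )
        trend_rows.append(tr._asdict())
    trends = pd.DataFrame(trend_rows)
    trends["bonferroni_m"] = dissim_m
    trends["bonferroni_threshold"] = bonferroni_threshold(config.alpha, dissim_m).rounded
    trend_path = _write("dissimilarity_trends.csv", trends)

    # --- context composition counts (per individual x age class) ---
    comp = (
        calls.groupby(["individual", "age_class", "context"], sort=True)
        .size()
        .rename("n_calls")
        .reset_index()
    )
    comp_path = _write("context_composition.csv", comp)

    # --- manifest with conservation check ---
    per_class_counts = {
        ac: int((calls["age_class"] == ac).sum()) for ac in age_classes
    }
    total = int(len(calls))
    assert check_partition_conservation(list(per_class_counts.values()), total)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "filter_log": filter_log,
        "n_calls_total": total,
        "n_calls_per_age_class": per_class_counts,
        "bonferroni": {
            "pic_trend": {"m": pic_thr.m, "threshold": pic_thr.rounded},
            "dissimilarity_trend": {
                "m": dissim_m,
                "threshold": bonferroni_threshold(config.alpha, dissim_m).rounded,
            },
        },
        "outputs": {
            "pdfa": pdfa_path.name,
            "pic": pic_path.name,
            "dissimilarity_records": rec_path.name,
            "dissimilarity_trends": trend_path.name,
            "context_composition": comp_path.name,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)

    return {
        "pdfa": pdfa_path,
        "pic": pic_path,
        "dissimilarity_records": rec_path,
        "dissimilarity_trends": trend_path,
        "context_composition": comp_path,
        "manifest": manifest_path,
        "calls": calls,
    }
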