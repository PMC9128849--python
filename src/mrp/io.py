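"""Canonical response-table schema, readers/writers, exclusion filtering,
run configuration and the end-to-end pipeline.

The canonical format is plain CSV with a versioned header comment line
(``# mrp-response-v1``).  Catch-trial rows carry ``is_catch=True`` and a
``catch_correct`` flag but no patch fields; probe rows carry the full patch
description and a dxc code consistent with (decision, confidence).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, design, sdt, simulate
from .exceptions import SchemaError

log = logging.getLogger(__name__)

SCHEMA_VERSION = "mrp-response-v1"

COLUMNS = [
    "participant_id", "experiment", "trial_index", "image_pair_id",
    "initial_congruence", "probe_index", "patch_type", "location",
    "eccentricity_class", "decision", "confidence", "dxc",
    "is_catch", "catch_correct",
]

_DTYPES = {"trial_index": int, "probe_index": int, "location": int,
           "confidence": int, "dxc": int}


def write_responses(df: pd.DataFrame, path) -> None:
    """Write the canonical CSV (versioned comment header + column row)."""
    path = Path(path)
    out = df.reindex(columns=[c for c in COLUMNS if c in df.columns]
                     + [c for c in df.columns if c not in COLUMNS])
    with path.open("w", newline="") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        out.to_csv(fh, index=False)


def validate_responses(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Return (row, message) diagnostics for every schema violation."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return [(-1, f"missing columns: {missing}")]
    problems: list[tuple[int, str]] = []

    def _flag(mask, fmt):
        for i in df.index[mask]:
            problems.append((i, fmt(df.loc[i])))

    is_catch = df["is_catch"].astype(bool)
    _flag(is_catch & df["catch_correct"].isna(),
          lambda r: "catch row without catch_correct")

    probe = ~is_catch
    bad_dec = probe & ~df["decision"].isin(sdt.DECISIONS)
    _flag(bad_dec, lambda r: f"bad decision {r['decision']!r}")
    bad_conf = probe & ~bad_dec & ~df["confidence"].isin(sdt.CONFIDENCES)
    _flag(bad_conf, lambda r: f"bad confidence {r['confidence']!r}")

    checkable = probe & ~bad_dec & ~bad_conf
    expected = np.where(df["decision"] == "yes",
                        df["confidence"], -df["confidence"])
    _flag(checkable & (df["dxc"] != expected),
          lambda r: f"dxc {r['dxc']} inconsistent with "
                    f"({r['decision']}, {r['confidence']})")

    bad_loc = probe & ~df["location"].isin(design.LOCATIONS)
    _flag(bad_loc, lambda r: f"bad location {r['location']!r}")
    expected_ecc = df["location"].map(design.LOCATION_CLASSES)
    _flag(probe & ~bad_loc & (df["eccentricity_class"] != expected_ecc),
          lambda r: f"eccentricity_class {r['eccentricity_class']!r} does not "
                    f"match location {r['location']}")
    _flag(probe & ~df["patch_type"].isin(design.PATCH_TYPES),
          lambda r: f"bad patch_type {r['patch_type']!r}")
    return sorted(problems)


def read_responses(path, dialect: str = "canonical",
                   validate: bool = True) -> pd.DataFrame:
    """Read and (by default) schema-validate a response table."""
    if dialect != "canonical":
        raise NotImplementedError(
            f"dialect {dialect!r} not available; only 'canonical' ships by default")
    # keep_default_na=False: the patch type "null" must survive as a string
    df = pd.read_csv(path, comment="#",
                     keep_default_na=False, na_values=[""],
                     dtype={"participant_id": str, "image_pair_id": str})
    for col, dt in _DTYPES.items():
        if col in df.columns:
            df[col] = df[col].fillna(0).astype(dt)
    for col in ("decision", "patch_type", "eccentricity_class", "initial_congruence"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    if "is_catch" in df.columns:
        df["is_catch"] = df["is_catch"].astype(bool)
    if validate:
        problems = validate_responses(df)
        if problems:
            raise SchemaError(problems)
    return df


def apply_exclusions(df: pd.DataFrame,
                     cutoff: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants whose catch accuracy is not strictly above ``cutoff``.

    Participants with no catch rows are retained with a warning.  Returns
    (filtered table, per-participant exclusion report).
    """
    is_catch = df["is_catch"].astype(bool)
    rows = []
    excluded_ids = []
    for part, grp in df.groupby("participant_id", sort=True):
        catch = grp.loc[is_catch.loc[grp.index]]
        n_catch = len(catch)
        if n_catch == 0:
            log.warning("participant %s has no catch trials; retained", part)
            rows.append({"participant_id": part, "n_catch": 0,
                         "catch_accuracy": float("nan"), "excluded": False,
                         "note": "no catch trials"})
            continue
        acc = float(catch["catch_correct"].astype(float).mean())
        excl = not (acc > cutoff)     # strict: exactly-at-cutoff is excluded
        if excl:
            excluded_ids.append(part)
        rows.append({"participant_id": part, "n_catch": n_catch,
                     "catch_accuracy": acc, "excluded": excl, "note": ""})
    report = pd.DataFrame(rows)
    filtered = df[~df["participant_id"].isin(excluded_ids)].copy()
    return filtered, report


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass(frozen=True)
class RunConfig:
    """Every constant that reaches an output is traceable to a field here."""
    experiment: str = "exp2"
    preset: str = "exp2-default"
    n_participants: int = 12
    n_pairs: int = 34
    seed: int = 0
    alpha: float = 0.05
    star_alpha: float = analysis.STAR_ALPHA
    double_star_alpha: float = analysis.DOUBLE_STAR_ALPHA
    catch_n: int = 13
    catch_options: int = 8
    catch_quantile: float = 0.99
    exclusions_enabled: bool = True
    diff_threshold: float = 10.0
    filter_scale: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Path]:
    """simulate -> exclude -> score -> report; returns paths of all artifacts.

    Fully deterministic for a given config (no timestamps, seeded RNG), so
    re-running with the same config reproduces byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config.hash()} seed={config.seed}"
    lines = [f"# {stamp}", f"# {json.dumps(config.to_dict(), sort_keys=True)}"]
    paths: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _write(name, df):
        p = out / f"{name}.csv"
        with p.open("w", newline="") as fh:
            fh.write(f"# {stamp}\n")
            df.to_csv(fh, index=False)
        paths[name] = p

    plan = _stage("design", lambda: design.build_design(
        config.experiment, config.n_participants, config.seed,
        n_pairs=config.n_pairs))
    params = simulate.get_preset(config.preset)
    responses = _stage("simulate", lambda: simulate.simulate_responses(
        plan, params, seed=config.seed))
    lines.append(f"simulate: {len(responses)} rows, "
                 f"{responses['participant_id'].nunique()} participants")

    if config.exclusions_enabled and responses["is_catch"].astype(bool).any():
        cutoff = design.catch_cutoff(config.catch_n, config.catch_options,
                                     config.catch_quantile)
        responses, report = _stage("exclude",
                                   lambda: apply_exclusions(responses, cutoff))
        _write("exclusions", report)
        lines.append(f"exclude: cutoff={cutoff}, "
                     f"{int(report['excluded'].sum())} excluded, "
                     f"{len(responses)} rows remain")
    else:
        lines.append("exclude: disabled")

    write_responses(responses, out / "responses.csv")
    paths["responses"] = out / "responses.csv"

    def _score():
        frames = []
        for task in sdt.TASKS:
            frames.append(analysis.auc_summary(responses, task))
        return pd.concat(frames, ignore_index=True)

    per_part = _stage("score", _score)
    _write("auc_participants", per_part)
    _write("auc_summary", analysis.summarize_auc(per_part))
    lines.append(f"score: {len(per_part)} participant x task x stratum rows")

    curves = _stage("report", lambda: analysis.proportion_curves(
        responses, {"present", "original"}, {"null"},
        labels=("present", "null")))
    _write("proportion_curves", curves)
    pairs = _stage("report", lambda: analysis.classify_all_pairs(
        responses, alpha=config.alpha))
    _write("pair_classification", pairs)
    _write("modelling_table", analysis.modelling_export(responses))
    lines.append(f"report: {len(pairs)} image pairs classified")

    logp = out / "run_log.txt"
    logp.write_text("\n".join(lines) + "\n")
    paths["log"] = logp
    return paths
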