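"""File I/O, configuration and the end-to-end pipeline.

CSV dialect is fixed (UTF-8, comma, "." decimal, mandatory header) so
fixtures are bit-exact.  Output files carry a provenance comment header
(package version, seed, config hash); readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .isotope_flux import IncubationSetup, compute_potentials, depth_fold_ratios
from .sip_gradient import DEFAULT_SHIFT_THRESHOLD, analyze_gradients
from .community import (
    METHANOTROPH_PANEL,
    TaxonCountTable,
    abundance_shift,
    clone_percentages,
    dominant_taxon,
    guild_composition,
    round_half_up,
)
from .group_stats import stats_summary

logger = logging.getLogger("sipflux")

__all__ = [
    "SCHEMAS",
    "PipelineConfig",
    "read_table",
    "write_table",
    "run_pipeline",
    "load_config",
]

# schema name -> (required columns, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "microcosm_measurements": (
        (
            "depth_label", "replicate_id", "treatment",
            "co2_concentration_pct",
            "atom13_co2_day90_pct", "atom13_co2_day0_pct",
            "soc_content_pct",
            "atom13_soc_day90_pct", "atom13_soc_day0_pct",
            "son_content_pct",
            "atom15_son_day90_pct", "atom15_son_day0_pct",
        ),
        (
            "co2_concentration_pct",
            "atom13_co2_day90_pct", "atom13_co2_day0_pct",
            "soc_content_pct",
            "atom13_soc_day90_pct", "atom13_soc_day0_pct",
            "son_content_pct",
            "atom15_son_day90_pct", "atom15_son_day0_pct",
        ),
    ),
    "gradient_fractions": (
        (
            "sample_id", "gene_name", "treatment_label",
            "buoyant_density_g_per_ml", "copy_number",
        ),
        ("buoyant_density_g_per_ml", "copy_number"),
    ),
    "community_counts": (
        ("sample_id", "depth_label", "timepoint", "taxon", "count"),
        ("count",),
    ),
    "clone_counts": (
        ("library_id", "domain", "depth_label", "taxon", "clone_count"),
        ("clone_count",),
    ),
}


class SchemaError(ValueError):
    """Input table does not match its declared schema."""


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming missing columns, and ValueError
    with 1-based data line numbers for unparseable numeric cells.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    required, numeric = SCHEMAS[schema_name]
    table = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for schema "
            f"{schema_name!r}"
        )
    table = table[list(required)]
    for col in numeric:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{path}: unparseable numeric value {table[col][bad.idxmax()]!r} "
                f"in column {col!r} near line {line}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} near line {line}")
        table[col] = converted
    return table


def _provenance(seed: int | None, config_hash: str | None) -> str:
    parts = [f"version={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return "# sipflux " + " ".join(parts)


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance(seed, config_hash) + "\n")
        table.to_csv(fh, index=False)
    return path


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, constants and thresholds for one end-to-end run."""

    microcosm_csv: str | None = None
    gradient_csv: str | None = None
    community_csv: str | None = None
    clone_csv: str | None = None
    outdir: str = "sipflux_out"
    setup: IncubationSetup = field(default_factory=IncubationSetup)
    shift_threshold_g_per_ml: float = DEFAULT_SHIFT_THRESHOLD
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def hash(self) -> str:
        # analysis-relevant parameters only: where outputs land is not
        # part of the scientific configuration
        payload = {
            k: (v if not isinstance(v, IncubationSetup) else vars(v))
            for k, v in vars(self).items()
            if k != "outdir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {
        "microcosm_csv", "gradient_csv", "community_csv", "clone_csv",
        "outdir", "setup", "shift_threshold_g_per_ml", "alpha", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    setup = IncubationSetup(**raw.pop("setup", {}))
    return PipelineConfig(setup=setup, **raw)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run flux -> gradient -> community -> stats -> report.

    Missing or empty optional inputs skip their stage with a warning.
    Returns the in-memory result bundle; files are written to
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    bundle: dict[str, object] = {"config_hash": chash}

    # --- flux stage
    if config.microcosm_csv and Path(config.microcosm_csv).exists():
        logger.info("flux stage: %s", config.microcosm_csv)
        meas = read_table(config.microcosm_csv, "microcosm_measurements")
        potentials = compute_potentials(meas, config.setup)
        write_table(potentials, outdir / "potentials.csv", config.seed, chash)
        labeled = potentials[potentials["treatment"] == "labeled"]
        depth_means = labeled.groupby("depth_label", sort=False).agg(
            total_ch4=("total_ch4_oxidation", "mean"),
            n2=("n2_fixation", "mean"),
            co2_fraction=("co2_fraction", "mean"),
        )
        bundle["potentials"] = potentials
        bundle["depth_means"] = depth_means
        bundle["ch4_fold_ratios"] = depth_fold_ratios(
            depth_means["total_ch4"].to_dict()
        )
        bundle["n2_fold_ratios"] = depth_fold_ratios(depth_means["n2"].to_dict())
        stats_frames = [
            stats_summary(labeled, col, alpha=config.alpha)
            for col in ("total_ch4_oxidation", "n2_fixation")
        ]
        stats = pd.concat(stats_frames, ignore_index=True)
        write_table(stats, outdir / "stats_summary.csv", config.seed, chash)
        bundle["stats_summary"] = stats
    else:
        logger.warning("flux stage skipped: no microcosm input")

    # --- gradient stage
    if config.gradient_csv and Path(config.gradient_csv).exists():
        fractions = read_table(config.gradient_csv, "gradient_fractions")
        if len(fractions):
            logger.info("gradient stage: %s", config.gradient_csv)
            calls = analyze_gradients(
                fractions, threshold_g_per_ml=config.shift_threshold_g_per_ml
            )
            write_table(calls, outdir / "labeling_calls.csv", config.seed, chash)
            bundle["labeling_calls"] = calls
        else:
            logger.warning("gradient stage skipped: empty fractions table")
    else:
        logger.warning("gradient stage skipped: no gradient input")

    # --- community stage
    if config.community_csv and Path(config.community_csv).exists():
        logger.info("community stage: %s", config.community_csv)
        long = read_table(config.community_csv, "community_counts")
        table = TaxonCountTable.from_long(long)
        guild = guild_composition(table, METHANOTROPH_PANEL)
        write_table(
            guild.reset_index(), outdir / "guild_composition.csv", config.seed, chash
        )
        bundle["guild_composition"] = guild
        shifts = _depth_shifts(guild, table.meta)
        if shifts is not None:
            write_table(shifts, outdir / "shifts.csv", config.seed, chash)
            bundle["shifts"] = shifts
    else:
        logger.warning("community stage skipped: no community input")

    # --- clone stage
    if config.clone_csv and Path(config.clone_csv).exists():
        logger.info("clone stage: %s", config.clone_csv)
        clones = read_table(config.clone_csv, "clone_counts")
        rows = []
        for lib, grp in clones.groupby("library_id", sort=True):
            counts = dict(zip(grp["taxon"], grp["clone_count"].astype(int)))
            pct = clone_percentages(counts)
            dom = dominant_taxon(pct)
            for taxon, p in pct.items():
                rows.append(
                    {
                        "library_id": lib,
                        "domain": grp["domain"].iloc[0],
                        "depth_label": grp["depth_label"].iloc[0],
                        "taxon": taxon,
                        "percent": p,
                        "is_dominant": taxon == dom,
                    }
                )
        clone_pct = pd.DataFrame(rows)
        write_table(clone_pct, outdir / "clone_percentages.csv", config.seed, chash)
        bundle["clone_percentages"] = clone_pct
    else:
        logger.warning("clone stage skipped: no clone input")

    _write_report(bundle, outdir / "report.md", config)
    return bundle


def _depth_shifts(guild: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame | None:
    """Day-0 -> day-90 shift per depth and taxon from within-guild RA."""
    if not {"depth_label", "timepoint"} <= set(meta.columns):
        return None
    rows = []
    for depth, sub in meta.groupby("depth_label", sort=False):
        by_time = {t: s for s, t in sub["timepoint"].items()}
        t0, t90 = by_time.get("day0"), by_time.get("day90")
        if t0 is None or t90 is None:
            continue
        for taxon in guild.columns:
            shift = abundance_shift(
                float(guild.loc[t0, taxon]), float(guild.loc[t90, taxon]), str(taxon)
            )
            rows.append(
                {
                    "depth_label": depth,
                    "taxon": shift.taxon,
                    "ra_initial_pct": shift.ra_initial_pct,
                    "ra_final_pct": shift.ra_final_pct,
                    "pp_change": shift.pp_change,
                    "fold_change": shift.fold_change,
                }
            )
    return pd.DataFrame(rows) if rows else None


def _write_report(bundle: Mapping[str, object], path: Path, config: PipelineConfig) -> None:
    lines = [
        "# SIP pipeline report",
        "",
        f"- sipflux version: {__version__}",
        f"- seed: {config.seed}",
        f"- config hash: {bundle['config_hash']}",
        "",
    ]
    if "depth_means" in bundle:
        lines += ["## Potentials (nmol per g dws per day)", ""]
        dm: pd.DataFrame = bundle["depth_means"]  # type: ignore[assignment]
        stats: pd.DataFrame = bundle["stats_summary"]  # type: ignore[assignment]
        for depth, row in dm.iterrows():
            letter_ch4 = _letter(stats, "total_ch4_oxidation", depth)
            letter_n2 = _letter(stats, "n2_fixation", depth)
            lines.append(
                f"- {depth}: CH4 oxidation {row['total_ch4']:.2f} "
                f"(CO2 share {100 * row['co2_fraction']:.0f}%) [{letter_ch4}]; "
                f"N2 fixation {row['n2']:.2f} [{letter_n2}]"
            )
        lines.append("")
        lines += ["### Fold ratios (1-decimal display)", ""]
        for label, key in (("CH4", "ch4_fold_ratios"), ("N2", "n2_fold_ratios")):
            for (a, b), r in bundle[key].items():  # type: ignore[union-attr]
                if not math.isnan(r):
                    lines.append(f"- {label} {a}/{b}: {round_half_up(r, 1)}")
        lines.append("")
    if "labeling_calls" in bundle:
        lines += ["## Gradient labeling calls", ""]
        calls: pd.DataFrame = bundle["labeling_calls"]  # type: ignore[assignment]
        for _, c in calls.iterrows():
            verdict = "labeled" if c["is_labeled"] else "not labeled"
            lines.append(
                f"- {c['gene_name']}: peak {c['peak_bd_labeled']:.3f} vs "
                f"{c['peak_bd_control']:.3f} g/mL (shift "
                f"{c['shift_g_per_ml']:+.3f}) -> {verdict}"
            )
        lines.append("")
    if "clone_percentages" in bundle:
        lines += ["## Dominant clone-library taxa", ""]
        cp: pd.DataFrame = bundle["clone_percentages"]  # type: ignore[assignment]
        for _, c in cp[cp["is_dominant"]].iterrows():
            lines.append(
                f"- {c['library_id']}: {c['taxon']} ({c['percent']:.2f}%)"
            )
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def _letter(stats: pd.DataFrame, variable: str, depth: str) -> str:
    row = stats[(stats["variable"] == variable) & (stats["depth_label"] == depth)]
    return row["letters"].iloc[0] if len(row) else ""
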