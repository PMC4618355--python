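"""Table and FASTA input/output, run configuration, and the end-to-end pipeline.

The canonical on-disk dialect is TSV (UTF-8, header row mandatory, "." as
decimal separator); CSV is accepted on read.  Missing numeric entries are
encoded as "n.d." (case-insensitive) or an empty cell.  Optional XLSX
ingestion is available for supplementary-style workbooks via a
column-mapping dictionary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .fitness_landscape import (
    STRAIN_COLUMNS,
    FluxFitnessFit,
    fit_flux_model,
    landscape_report,
    distribution_shift,
    spearman_matrix,
)
from .proteome import (
    GeneGroupSet,
    group_shift_analysis,
    lrpa,
    shifts_to_frame,
    zscore_proteome,
)

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_strain_table",
    "write_strain_table",
    "read_fasta",
    "write_fasta",
    "read_proteome_matrix",
    "read_gene_groups",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"n.d.", "nd", "n.d", ""}

REQUIRED_STRAIN_COLUMNS = ["strain_id", "growth_rate_naive", "growth_rate_evolved"]

#: default properties entering the cross-correlation matrix
CORRELATION_PROPERTIES = [
    "growth_rate_naive",
    "growth_rate_evolved",
    "tm_c",
    "kcat_over_km",
    "abundance_total_naive",
    "abundance_total_evolved",
    "promoter_activity_naive",
    "net_charge",
    "gc_percent",
    "identity_percent",
    "cai",
]


class SchemaError(ValueError):
    """A required column could not be resolved in an input table."""


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, sep=sep, dtype=str)


def read_strain_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a strain property table (TSV/CSV/XLSX) into typed records.

    ``column_map`` renames source columns to the canonical schema (useful
    for supplementary workbooks with verbose headers).  "n.d." and blank
    cells parse as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_table(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    for col in REQUIRED_STRAIN_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} not found in {path.name}")
    df = pd.DataFrame(index=raw.index)
    for col in STRAIN_COLUMNS:
        if col not in raw.columns:
            df[col] = "" if col in ("strain_id", "species") else float("nan")
            continue
        if col in ("strain_id", "species"):
            df[col] = raw[col].fillna("").astype(str)
            continue
        cleaned = raw[col].fillna("").astype(str).str.strip()
        cleaned = cleaned.where(~cleaned.str.lower().isin(MISSING_TOKENS), other=None)
        try:
            df[col] = pd.to_numeric(cleaned)
        except (ValueError, TypeError) as exc:
            bad = cleaned[pd.to_numeric(cleaned, errors="coerce").isna() & cleaned.notna()]
            line = bad.index[0] + 2  # header + 1-based
            raise ValueError(
                f"unparseable value {bad.iloc[0]!r} in column {col!r}, line {line}"
            ) from exc
    n_missing = int(df[[c for c in STRAIN_COLUMNS if c not in ("strain_id", "species")]].isna().sum().sum())
    logger.info("read %d strain records (%d missing cells) from %s", len(df), n_missing, path)
    return df


def write_strain_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g", na_rep="n.d.")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving id -> sequence map; duplicate ids are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else title
            if name in out:
                raise ValueError(f"duplicate FASTA id {name!r} in {path.name}")
            out[name] = seq.upper()
    if not out:
        raise ValueError(f"no records in {path}")
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_proteome_matrix(path: str | Path, already_log10: bool = False) -> pd.DataFrame:
    """Gene x strain matrix: first column gene_id, remaining columns strains."""
    path = Path(path)
    raw = _read_table(path)
    raw = raw.set_index(raw.columns[0])
    mat = raw.apply(pd.to_numeric, errors="coerce")
    mat.index.name = "gene_id"
    if already_log10:
        mat = 10.0 ** mat
    return mat


def read_gene_groups(path: str | Path) -> GeneGroupSet:
    """Two-column (group_id, gene_id) TSV into a gene-group set."""
    df = _read_table(Path(path))
    if df.shape[1] < 2:
        raise SchemaError("gene-group file needs two columns: group_id, gene_id")
    return GeneGroupSet.from_frame(df.iloc[:, :2])


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (written next to outputs)."""

    strain_table: str
    out_dir: str
    phase: str = "naive"
    abundance_field: str = "total"
    exclude: tuple[str, ...] = ()
    proteome_pre: str | None = None
    proteome_post: str | None = None
    gene_groups: str | None = None
    alpha: float = 0.01
    min_group_size: int = 5
    residual_threshold: float = 0.1
    correlation_properties: list[str] = field(default_factory=lambda: list(CORRELATION_PROPERTIES))
    seed: int = 0


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis end to end and write the report bundle.

    Stages: strain-table ingest -> flux-fitness fit (both phases) ->
    cross-property Spearman matrix -> growth/abundance distribution shifts ->
    per-strain landscape report -> (optional) proteome z-scoring, pairwise
    correlations and gene-group KS shifts.  Each output lands in
    ``config.out_dir``; the resolved config and input checksums are written
    alongside for reproducibility.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}}

    table = read_strain_table(config.strain_table)

    fits: dict[str, FluxFitnessFit] = {}
    for phase in ("naive", "evolved"):
        try:
            fit = fit_flux_model(
                table, phase=phase, abundance_field=config.abundance_field,
                exclude=config.exclude,
            )
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"stage fit_flux_model[{phase}] failed: {exc}") from exc
        fits[phase] = fit
        with open(out / f"fit_{phase}.json", "w") as fh:
            json.dump(
                {
                    "a": fit.a, "b": fit.b, "r_squared": fit.r_squared,
                    "p_value": fit.p_value, "excluded": list(fit.excluded_ids),
                    "dropped_missing": list(fit.dropped_missing), "n_used": fit.n_used,
                },
                fh, indent=2,
            )
        rep = landscape_report(
            table, fit, phase=phase, abundance_field=config.abundance_field,
            residual_threshold=config.residual_threshold,
        )
        rep.to_csv(out / f"landscape_{phase}.tsv", sep="\t", index=False, float_format="%.9g")
    report["stages"]["fit_flux_model"] = {p: vars(f)["a"] for p, f in fits.items()}

    corr = spearman_matrix(table, [c for c in config.correlation_properties if c in table.columns])
    corr.r.to_csv(out / "corr_r.tsv", sep="\t", float_format="%.9g")
    corr.p.to_csv(out / "corr_p.tsv", sep="\t", float_format="%.9g")
    report["stages"]["spearman_matrix"] = {"n_properties": len(corr.properties)}

    shift = distribution_shift(
        table["growth_rate_naive"].dropna(), table["growth_rate_evolved"].dropna()
    )
    with open(out / "growth_shift.json", "w") as fh:
        json.dump(shift, fh, indent=2)
    report["stages"]["distribution_shift"] = shift

    if config.proteome_pre and config.proteome_post and config.gene_groups:
        pre = read_proteome_matrix(config.proteome_pre)
        post = read_proteome_matrix(config.proteome_post)
        groups = read_gene_groups(config.gene_groups)
        z_pre = zscore_proteome(lrpa(pre))
        z_post = zscore_proteome(lrpa(post))
        z_pre.to_csv(out / "z_pre.tsv", sep="\t", float_format="%.9g")
        z_post.to_csv(out / "z_post.tsv", sep="\t", float_format="%.9g")
        all_shifts = []
        for strain in z_pre.columns:
            if strain not in z_post.columns:
                continue
            res = group_shift_analysis(
                z_pre[strain], z_post[strain], groups,
                alpha=config.alpha, min_size=config.min_group_size,
            )
            frame = shifts_to_frame(res)
            frame.insert(0, "strain", strain)
            all_shifts.append(frame)
        shifts = pd.concat(all_shifts, ignore_index=True) if all_shifts else pd.DataFrame()
        shifts.to_csv(out / "shifts.tsv", sep="\t", index=False, float_format="%.9g")
        report["stages"]["group_shift_analysis"] = {"n_rows": len(shifts)}
    elif config.proteome_pre or config.proteome_post or config.gene_groups:
        logger.warning("incomplete proteome inputs; proteome stages skipped")
        report["stages"]["group_shift_analysis"] = "skipped (incomplete inputs)"

    resolved = asdict(config)
    resolved["exclude"] = list(config.exclude)
    resolved["input_checksums"] = {
        "strain_table": _checksum(config.strain_table),
        **{
            k: _checksum(getattr(config, k))
            for k in ("proteome_pre", "proteome_post", "gene_groups")
            if getattr(config, k)
        },
    }
    with open(out / "run_config.json", "w") as fh:
        json.dump({"config": resolved, "report": report}, fh, indent=2)
    return report
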