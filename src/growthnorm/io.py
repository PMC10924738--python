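"""Table dialects, VCF ingestion, run configuration, provenance headers.

All observational tables are long (tidy) CSVs with explicit keys and one
value column; days are integer days after sowing.  Every file written by
the package carries a provenance comment header (# key: value) with the
package version and a config hash; readers skip '#' lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomics import GenotypeMatrix, GenomicKernel

__all__ = [
    "read_genotypes",
    "read_genotypes_vcf",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "write_table",
    "read_table",
    "write_kernel",
    "read_kernel",
    "load_config",
    "config_hash",
    "validate_run",
]

PACKAGE_VERSION = "0.1.0"


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance_header(config: dict | None) -> str:
    h = config_hash(config) if config else "none"
    return f"# growthnorm {PACKAGE_VERSION}\n# config_hash: {h}\n"


def write_table(df: pd.DataFrame, path, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_genotypes_csv(path) -> GenotypeMatrix:
    """Score-matrix CSV: genotypes in rows (index column), markers in columns."""
    df = pd.read_csv(path, comment="#", index_col=0)
    return GenotypeMatrix(
        df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_genotypes_csv(geno: GenotypeMatrix, path, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        geno.to_frame().to_csv(fh, index_label="genotype")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """VCF genotypes: biallelic records to -1/0/1, others skipped.

    Missing calls become NaN.  The count of skipped non-biallelic records
    is stored on the result as ``n_skipped``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF")
    cols, ids = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :2]
        score = gt.sum(axis=1).astype(float) - 1.0
        score[(gt < 0).any(axis=1)] = np.nan
        cols.append(score)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError("no biallelic records in VCF")
    out = GenotypeMatrix(np.column_stack(cols), samples, ids)
    out.n_skipped = n_skipped  # type: ignore[attr-defined]
    return out


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "csv"
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "csv":
        return read_genotypes_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_kernel(kernel: GenomicKernel, path, config: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(kernel.matrix, index=kernel.genotype_ids, columns=kernel.genotype_ids)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index_label="genotype")
    meta = {
        "kind": kernel.kind,
        "bandwidth": kernel.bandwidth,
        "provenance": kernel.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def read_kernel(path) -> GenomicKernel:
    df = pd.read_csv(path, comment="#", index_col=0)
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return GenomicKernel(
        df.to_numpy(float),
        [str(i) for i in df.index],
        kind=meta.get("kind", "linear"),
        bandwidth=meta.get("bandwidth"),
        provenance=meta.get("provenance", {}),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


GRIDS = {
    "Q": (3, 4, 5),
    "lambda0": (10.0, 30.0, 50.0, 70.0),
    "mtry": (5, 10, 15, 20, 25, 30),
}


def validate_run(
    config: dict,
    design: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    moisture: pd.DataFrame | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> dict:
    """Cross-check config and tables; returns {'fatal': [...], 'warning': [...]}."""
    report = {"fatal": [], "warning": []}
    for key, grid in GRIDS.items():
        if key in config and config[key] not in grid:
            report["warning"].append(
                f"{key}={config[key]} outside the standard grid {grid}"
            )
    if design is not None and phenotypes is not None:
        unknown = set(phenotypes["plot_id"]) - set(design["plot_id"])
        if unknown:
            report["fatal"].append(
                f"phenotype plots not in design: {sorted(unknown)[:5]}"
            )
    if design is not None and genotypes is not None:
        missing = set(design["genotype"]) - set(genotypes.genotype_ids)
        if missing:
            report["fatal"].append(
                f"design genotypes absent from genotype matrix: {sorted(missing)[:5]}"
            )
    if design is not None and moisture is not None:
        bare = set(design["row"]) - set(moisture["row"])
        if bare:
            report["warning"].append(
                f"design rows without moisture measurements: {sorted(bare)[:5]}"
            )
    return report
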