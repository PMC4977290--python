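"""Readers and writers for genotype, phenotype and result files.

Primary exchange format is delimited text (TSV): genotype files have
accessions as rows, a first column of accession ids and a header of marker
ids, with dosages in {0, 1, 2}.  A minimal VCF reader (GT field to
alternate-allele dosage, biallelic sites only) is provided for
convenience.  All result files start with a provenance header comment
(tool version + config hash) and numbers are written with 6 significant
digits so identical runs produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kernels import GenotypeMatrix, GramMatrix, KernelSpec
from .mixed_model import MixedModelFit

logger = logging.getLogger("kernelgp")

__all__ = [
    "DataError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_gram",
    "write_gram",
    "write_fit_report",
    "read_fit_report",
    "write_marker_effects",
    "write_predictions",
    "maf_report",
    "provenance_header",
]


class DataError(ValueError):
    pass


def provenance_header(config: dict | None = None) -> str:
    digest = hashlib.md5(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# kernelgp {__version__} config_hash={digest}"


def maf_report(X: GenotypeMatrix) -> pd.DataFrame:
    maf = X.maf()
    return pd.DataFrame({"marker_id": X.marker_ids, "maf": maf})


def read_genotypes(
    path,
    fmt: str = "tsv",
    maf_min: float | None = None,
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a dosage matrix from TSV/CSV or a biallelic VCF.

    Missing entries are rejected with their row/column coordinates
    (imputation is a preprocessing step, not a feature).  With ``maf_min``
    set, markers at or below that minor allele frequency are dropped and
    the count logged — the conventional filter is MAF > 0.01.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"genotype file not found: {path}")
    if fmt == "vcf":
        return _read_vcf(path, maf_min=maf_min)
    if fmt != "tsv":
        raise DataError(f"unknown genotype format {fmt!r}")
    sep = sep or ("," if path.suffix.lower() == ".csv" else "\t")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[1] < 1:
        raise DataError(f"malformed genotype header in {path}")
    values = df.to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DataError(
            f"missing genotype at accession {df.index[i]!r}, marker "
            f"{df.columns[j]!r} in {path}; impute before loading"
        )
    X = GenotypeMatrix(
        values,
        coding="raw_012",
        accession_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
    )
    return _apply_maf_filter(X, maf_min)


def _apply_maf_filter(X: GenotypeMatrix, maf_min: float | None) -> GenotypeMatrix:
    maf = X.maf()
    logger.info("MAF: min %.4f median %.4f across %d markers", maf.min(), np.median(maf), X.p)
    if maf_min is None:
        return X
    keep = maf > maf_min
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF filter > %g dropped %d of %d markers", maf_min, dropped, X.p)
    if keep.sum() == 0:
        raise DataError("MAF filter removed every marker")
    return GenotypeMatrix(
        X.values[:, keep],
        coding="raw_012",
        accession_ids=list(X.accession_ids),
        marker_ids=[m for m, k in zip(X.marker_ids, keep) if k],
    )


def _read_vcf(path: Path, maf_min: float | None) -> GenotypeMatrix:
    """Minimal VCF support via cyvcf2: GT field -> alternate-allele dosage."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise DataError("VCF input requires the cyvcf2 package") from exc
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        marker_ids: list[str] = []
        rows: list[list[float]] = []
        skipped = 0
        for var in vcf:
            if len(var.ALT) != 1:  # non-biallelic site
                skipped += 1
                continue
            dosages = []
            for gt in var.genotypes:  # [allele0, allele1, phased]
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    raise DataError(
                        f"missing genotype at {var.CHROM}:{var.POS} in {path}"
                    )
                dosages.append(float(sum(alleles)))
            marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            rows.append(dosages)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"malformed VCF {path}: {exc}") from exc
    if skipped:
        logger.info("skipped %d non-biallelic VCF records", skipped)
    if not rows:
        raise DataError(f"no usable biallelic records in {path}")
    X = GenotypeMatrix(
        np.asarray(rows, dtype=float).T,
        coding="raw_012",
        accession_ids=samples,
        marker_ids=marker_ids,
    )
    return _apply_maf_filter(X, maf_min)


def write_genotypes(X: GenotypeMatrix, path, config: dict | None = None) -> None:
    df = pd.DataFrame(X.values, index=X.accession_ids, columns=X.marker_ids)
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", index_label="accession")


def read_phenotypes(path, sep: str = "\t") -> pd.Series:
    """Two-column (accession, value) table; returns an id-indexed Series."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[1] != 1:
        raise DataError(f"phenotype file must have exactly one value column, got {df.shape[1]}")
    s = df.iloc[:, 0].astype(float)
    if s.isna().any():
        raise DataError(f"missing phenotype for accession {s.index[s.isna()][0]!r}")
    s.index = s.index.astype(str)
    return s


def write_phenotypes(ids, values, path, name: str = "phenotype", config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        pd.Series(np.asarray(values, float), index=ids, name=name).to_csv(
            fh, sep="\t", float_format="%.6g", index_label="accession"
        )


def write_gram(K: GramMatrix, path, config: dict | None = None) -> None:
    ids = K.accession_ids or [f"acc{i}" for i in range(K.n)]
    df = pd.DataFrame(K.values, index=ids, columns=ids)
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", index_label="accession")


def read_gram(path, spec: KernelSpec | None = None) -> GramMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return GramMatrix(
        df.to_numpy(dtype=float),
        spec=spec or KernelSpec("linear"),
        accession_ids=[str(i) for i in df.index],
    )


def write_fit_report(
    fit: MixedModelFit,
    path,
    accession_ids=None,
    center_means: np.ndarray | None = None,
    config: dict | None = None,
) -> None:
    """Serialize a fit (variances, fixed effects, dual variables) to JSON."""
    spec = fit.spec
    payload = {
        "tool": f"kernelgp {__version__}",
        "config_hash": provenance_header(config).split("config_hash=")[1],
        "kernel": None if spec is None else {
            "family": spec.family,
            "decay_h": spec.decay_h,
            "degree_d": spec.degree_d,
            "offset_c": spec.offset_c,
        },
        "sigma2_g": fit.sigma2_g,
        "sigma2_e": fit.sigma2_e,
        "lambda_hat": fit.lambda_hat,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "at_floor": fit.at_floor,
        "restricted_loglik_trace": [float(x) for x in fit.reml_trace],
        "beta_fixed": [float(b) for b in fit.beta_fixed],
        "alpha_hat": [float(a) for a in fit.alpha_hat],
        "accession_ids": list(accession_ids) if accession_ids is not None else None,
        "center_means": None if center_means is None else [float(m) for m in center_means],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_marker_effects(marker_ids, effects, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        pd.Series(np.asarray(effects, float), index=marker_ids, name="effect").to_csv(
            fh, sep="\t", float_format="%.6g", index_label="marker_id"
        )


def write_predictions(ids, predictions, path, config: dict | None = None) -> None:
    write_phenotypes(ids, predictions, path, name="prediction", config=config)
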