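"""Readers and writers for the external formats the toolkit touches.

Supported formats:

* VCF v4.x (GT field, diploid biallelic SNPs) — read through cyvcf2,
  written as minimal text VCF.
* PLINK-style text genotype table: ``##COUNTED=REF`` header, one
  ``##MARKER`` line per SNP (id, chrom, bp, ref, alt), then a tab-separated
  samples x markers code table with ``NA`` for missing.
* PLINK ``.frq.strat``-style stratified allele-frequency TSV
  (CHR SNP CLST A1 A2 MAF NCHROBS; one row per marker x population).
* ADMIXTURE-style ``.Q`` (whitespace-separated, one row per individual).
* Two-column TSV sample -> population labels.
* Ranking TSV (marker_id, chrom, bp, method, score, rank).
"""

from __future__ import annotations

import logging
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    ContractError,
    GenotypeMatrix,
    LeikitError,
    MarkerScoreVector,
    PopAlleleFreqTable,
)

logger = logging.getLogger(__name__)


class ParseError(LeikitError):
    """A record in an input file does not parse under the named standard."""


class LabelingError(LeikitError):
    """The labels file does not cover every sample."""


class CompletenessError(LeikitError):
    """A stratified frequency table is missing marker x population rows."""


# ---------------------------------------------------------------------------
# genotype matrices


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    labels_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes from VCF or the PLINK-style text table.

    Returns a matrix sorted by (chrom, bp).  Multi-allelic and non-SNP VCF
    records are skipped; the skip count is logged.  When ``labels_path`` is
    given it must assign a population to every sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        G = _read_vcf(path)
    elif format == "plink_text":
        G = _read_plink_text(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    G = _sort_by_position(G)
    if labels_path is not None:
        labels = read_labels(labels_path)
        missing = [s for s in G.sample_ids if s not in labels]
        if missing:
            raise LabelingError(
                f"labels file does not cover samples: {', '.join(missing)}"
            )
        G.population_labels = [labels[s] for s in G.sample_ids]
    return G


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    chrom: list[str] = []
    bp: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        bp.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        col[gt == 0] = 2  # two reference alleles
        col[gt == 1] = 1
        col[gt == 3] = 0
        columns.append(col)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP records in %s", n_skipped, path)
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        chrom=np.asarray(chrom, dtype=object),
        bp=np.asarray(bp, dtype=np.int64),
        ref_allele=np.asarray(ref, dtype=object),
        alt_allele=np.asarray(alt, dtype=object),
        codes=codes,
    )


def _read_plink_text(path: Path) -> GenotypeMatrix:
    markers: list[tuple[str, str, int, str, str]] = []
    header: list[str] | None = None
    rows: list[tuple[str, list[int]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##MARKER"):
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ParseError(f"{path}:{lineno}: malformed ##MARKER line")
                markers.append(
                    (parts[1], parts[2], int(parts[3]), parts[4], parts[5])
                )
            elif line.startswith("##"):
                continue
            elif header is None:
                header = line.split("\t")
                if header[0] != "sample_id":
                    raise ParseError(f"{path}:{lineno}: header must start with sample_id")
            else:
                parts = line.split("\t")
                if len(parts) != len(header):
                    raise ParseError(f"{path}:{lineno}: wrong number of fields")
                try:
                    codes = [
                        MISSING if tok == "NA" else int(tok) for tok in parts[1:]
                    ]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
                rows.append((parts[0], codes))
    if header is None:
        raise ParseError(f"{path}: no header row")
    ids = {m[0] for m in markers}
    if ids != set(header[1:]):
        raise ParseError(f"{path}: ##MARKER lines do not match header columns")
    by_id = {m[0]: m for m in markers}
    ordered = [by_id[mid] for mid in header[1:]]
    return GenotypeMatrix(
        sample_ids=[r[0] for r in rows],
        marker_ids=[m[0] for m in ordered],
        chrom=np.asarray([m[1] for m in ordered], dtype=object),
        bp=np.asarray([m[2] for m in ordered], dtype=np.int64),
        ref_allele=np.asarray([m[3] for m in ordered], dtype=object),
        alt_allele=np.asarray([m[4] for m in ordered], dtype=object),
        codes=np.asarray([r[1] for r in rows], dtype=np.int8),
    )


def _sort_by_position(G: GenotypeMatrix) -> GenotypeMatrix:
    order = sorted(
        range(G.n_markers), key=lambda j: (G.chrom[j], int(G.bp[j]), G.marker_ids[j])
    )
    if order == list(range(G.n_markers)):
        return G
    return G.subset_markers(order)


def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    """Write a genotype matrix as minimal text VCF or the PLINK-style table."""
    path = Path(path)
    if format == "vcf":
        _write_vcf(G, path)
    elif format == "plink_text":
        _write_plink_text(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_BY_CODE = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in dict.fromkeys(G.chrom.tolist()):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j in range(G.n_markers):
            gts = "\t".join(_GT_BY_CODE[int(c)] for c in G.codes[:, j])
            fh.write(
                f"{G.chrom[j]}\t{G.bp[j]}\t{G.marker_ids[j]}\t"
                f"{G.ref_allele[j]}\t{G.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_plink_text(G: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##COUNTED=REF\n")
        for j in range(G.n_markers):
            fh.write(
                f"##MARKER\t{G.marker_ids[j]}\t{G.chrom[j]}\t{G.bp[j]}\t"
                f"{G.ref_allele[j]}\t{G.alt_allele[j]}\n"
            )
        fh.write("sample_id\t" + "\t".join(G.marker_ids) + "\n")
        for i, sid in enumerate(G.sample_ids):
            toks = [
                "NA" if c == MISSING else str(int(c)) for c in G.codes[i]
            ]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id -> population name."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in labels.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# stratified allele-frequency tables

_FRQ_STRAT_COLS = ["CHR", "SNP", "CLST", "A1", "A2", "MAF", "NCHROBS"]


def read_freq_table(path: str | Path) -> PopAlleleFreqTable:
    """Read a PLINK ``.frq.strat``-style stratified frequency TSV.

    The A1 column is taken as the reference allele, so MAF is read as the
    reference-allele frequency f_j.  Diploid individual counts are recovered
    as NCHROBS / 2, rounded half up (a warning is emitted on odd NCHROBS).
    Every marker must be present for every population.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str, "SNP": str, "CLST": str})
    missing_cols = [c for c in _FRQ_STRAT_COLS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    if df["MAF"].min() < 0 or df["MAF"].max() > 1:
        bad = df.loc[(df["MAF"] < 0) | (df["MAF"] > 1), "SNP"].iloc[0]
        raise ContractError(f"{path}: frequency outside [0, 1] at marker {bad}")
    pops = list(dict.fromkeys(df["CLST"]))
    marker_order = list(dict.fromkeys(df["SNP"]))
    pivot = df.pivot_table(index="SNP", columns="CLST", values="MAF", aggfunc="first")
    incomplete = pivot.index[pivot.isna().any(axis=1)].tolist()
    if incomplete or len(pivot) != len(marker_order):
        raise CompletenessError(
            f"{path}: markers missing for some population: "
            + ", ".join(map(str, incomplete or marker_order))
        )
    pivot = pivot.loc[marker_order, pops]
    c = np.empty(len(pops), dtype=np.int64)
    for j, pop in enumerate(pops):
        nchrobs = df.loc[df["CLST"] == pop, "NCHROBS"]
        if (nchrobs % 2 != 0).any():
            warnings.warn(
                f"odd NCHROBS for population {pop}; rounding half up to individuals",
                stacklevel=2,
            )
        c[j] = int(math.floor(nchrobs.iloc[0] / 2 + 0.5))
    chrom_map = df.drop_duplicates("SNP").set_index("SNP")["CHR"]
    return PopAlleleFreqTable(
        marker_ids=marker_order,
        population_names=pops,
        f=pivot.to_numpy(dtype=float),
        c=c,
        chrom=chrom_map.loc[marker_order].to_numpy(dtype=object),
    )


def write_freq_table(F: PopAlleleFreqTable, path: str | Path) -> None:
    """Write the ``.frq.strat`` dialect (A1 = reference allele)."""
    with open(path, "w") as fh:
        fh.write(" ".join(_FRQ_STRAT_COLS) + "\n")
        for j, mid in enumerate(F.marker_ids):
            ch = F.chrom[j] if F.chrom is not None else "1"
            for q, pop in enumerate(F.population_names):
                fh.write(
                    f"{ch} {mid} {pop} A C {F.f[j, q]:.8f} {2 * int(F.c[q])}\n"
                )


# ---------------------------------------------------------------------------
# Q matrices

_SIMPLEX_TOL = 1e-8


def write_q_matrix(q: np.ndarray, path: str | Path) -> None:
    """Write an ADMIXTURE-style ``.Q`` file (rows must lie on the simplex)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if np.any(q < -_SIMPLEX_TOL) or np.max(np.abs(q.sum(axis=1) - 1)) > _SIMPLEX_TOL:
        bad = int(np.argmax(np.abs(q.sum(axis=1) - 1)))
        raise ContractError(f"Q row {bad} not on the simplex")
    np.savetxt(path, q, fmt="%.6f", delimiter=" ")


def read_q_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, dtype=float))


# ---------------------------------------------------------------------------
# rankings


def write_ranking(scores: MarkerScoreVector, path: str | Path) -> None:
    """Write a ranking TSV: marker_id, chrom, bp, method, score, rank."""
    if scores.rank is None:
        raise ContractError("ranking not attached; call rank_markers first")
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tbp\tmethod\tscore\trank\n")
        for i in np.argsort(scores.rank):
            ch = scores.chrom[i] if scores.chrom is not None else "."
            pos = scores.bp[i] if scores.bp is not None else "."
            fh.write(
                f"{scores.marker_ids[i]}\t{ch}\t{pos}\t{scores.method_name}\t"
                f"{scores.scores[i]:.10g}\t{scores.rank[i]}\n"
            )


def read_ranking(path: str | Path) -> MarkerScoreVector:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    return MarkerScoreVector(
        method_name=str(df["method"].iloc[0]),
        marker_ids=df["marker_id"].tolist(),
        scores=df["score"].to_numpy(dtype=float),
        rank=df["rank"].to_numpy(dtype=np.int64),
        chrom=df["chrom"].to_numpy(dtype=object),
        bp=None if (df["bp"] == ".").any() else df["bp"].to_numpy(dtype=np.int64),
    )
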