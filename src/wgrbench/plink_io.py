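"""PLINK .bed/.bim/.fam reading and writing, plus a plain TSV dosage dialect.

The .bed codec implements the SNP-major binary layout: a 3-byte header
(0x6c, 0x1b, 0x01) followed by ceil(n/4) bytes per variant, two bits per
genotype, least significant pair first:

    00 homozygous A1 (dosage 2 copies of A1)   01 missing
    10 heterozygous (dosage 1)                 11 homozygous A2 (dosage 0)

Dosages count copies of the A1 allele, matching the .bim allele order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_sim import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# code -> dosage (A1 copies); 1 flags a missing genotype
_CODE_TO_DOSE = np.array([2, 0, 1, 0], dtype=np.int8)
_CODE_IS_MISSING = np.array([False, True, False, False])
_DOSE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed or inconsistent .bed/.bim/.fam triplet."""


def write_plink(G: GenotypeMatrix, prefix: str | Path,
                missing_mask: np.ndarray | None = None) -> None:
    prefix = Path(prefix)
    n, p = G.dosages.shape
    bim = pd.DataFrame(
        {
            "chrom": G.chromosome,
            "snp": G.marker_ids,
            "cm": 0.0,
            "pos": G.position_bp,
            "a1": G.allele_labels[:, 0],
            "a2": G.allele_labels[:, 1],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.individual_ids,
            "iid": G.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    codes = np.empty((p, n), dtype=np.uint8)
    for dose, code in _DOSE_TO_CODE.items():
        codes[(G.dosages.T == dose)] = code
    if missing_mask is not None:
        codes[np.asarray(missing_mask).T] = 0b01
    padded = np.zeros((p, 4 * n_bytes), dtype=np.uint8)
    padded[:, :n] = codes
    shaped = padded.reshape(p, n_bytes, 4)
    packed = (
        shaped[:, :, 0]
        | (shaped[:, :, 1] << 2)
        | (shaped[:, :, 2] << 4)
        | (shaped[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a .bed/.bim/.fam triplet.

    Returns the genotype matrix (missing entries stored as dosage 0) and a
    boolean n x p mask flagging the missing entries.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(prefix.with_suffix(ext))
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, p = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _MAGIC:
        raise PlinkFormatError("bad .bed magic bytes (not SNP-major PLINK 1 format)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != p * n_bytes:
        raise PlinkFormatError(
            f".bed payload has {body.size} bytes, expected {p * n_bytes}"
        )
    body = body.reshape(p, n_bytes)
    codes = np.empty((p, 4 * n_bytes), dtype=np.uint8)
    codes[:, 0::4] = body & 3
    codes[:, 1::4] = (body >> 2) & 3
    codes[:, 2::4] = (body >> 4) & 3
    codes[:, 3::4] = (body >> 6) & 3
    codes = codes[:, :n]
    dosages = _CODE_TO_DOSE[codes].T
    missing = _CODE_IS_MISSING[codes].T
    G = GenotypeMatrix(
        dosages=dosages,
        marker_ids=bim["snp"].to_numpy(dtype=str),
        chromosome=bim["chrom"].to_numpy(dtype=str),
        position_bp=bim["pos"].to_numpy(dtype=np.int64),
        allele_labels=np.stack(
            [bim["a1"].to_numpy(dtype=str), bim["a2"].to_numpy(dtype=str)], axis=1
        ),
        individual_ids=fam["iid"].to_numpy(dtype=str),
    )
    return G, missing


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text dosage dialect: one row per individual, one column per
    marker id (test-friendly mirror of the binary format)."""
    df = pd.DataFrame(G.dosages, index=G.individual_ids, columns=G.marker_ids)
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    p = df.shape[1]
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=np.int8),
        marker_ids=np.asarray(df.columns, dtype=str),
        chromosome=np.full(p, "1"),
        position_bp=10_000 * (np.arange(p) + 1),
        allele_labels=np.tile(np.array([["A", "B"]]), (p, 1)),
        individual_ids=np.asarray(df.index, dtype=str),
    )


def write_phenotypes(path: str | Path, individual_ids, values,
                     genetic_values=None) -> None:
    cols = {"FID": individual_ids, "IID": individual_ids, "y": values}
    if genetic_values is not None:
        cols["g"] = genetic_values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
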