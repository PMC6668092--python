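"""Readers and writers for PLINK1, GCTA GRM binary, and GCTA-style text files.

The PLINK1 ``.bed`` codec implements the SNP-major layout: three magic bytes
``0x6C 0x1B 0x01`` followed, per variant, by ceil(n/4) bytes of 2-bit codes
(sample i of a variant sits at bits ``2*(i % 4)`` of byte ``i // 4``)::

    00 -> 2   (homozygous A1)     01 -> missing
    10 -> 1   (heterozygous)      11 -> 0   (homozygous A2)

Dosages therefore count the A1 allele as read; after centering and scaling
the orientation only affects the sign of standardized genotypes, which is
irrelevant to the GRM.

The GCTA binary GRM triplet stores the lower triangle (diagonal included)
of the relatedness matrix row-major as little-endian float32 in
``.grm.bin``, sample IDs in ``.grm.id``, and optionally per-pair marker
counts in ``.grm.N.bin``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genomatrix import RawGenotypes

logger = logging.getLogger(__name__)

__all__ = ["read_plink", "write_plink", "read_gcta_grm", "write_gcta_grm",
           "read_pheno_covar"]

_BED_MAGIC = bytes([0x6C, 0x1B])
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
# dosage -> 2-bit code (missing handled separately)
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def read_plink(prefix: str) -> RawGenotypes:
    """Read a PLINK1 ``.bed/.bim/.fam`` triplet into dosages."""
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pid", "mid", "sex", "pheno"],
                      dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype=str)
    n, m = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a PLINK1 bed file (bad magic)")
    if raw[2] != 0x01:
        raise ValueError("sample-major PLINK1 bed files are not supported")
    bpv = (n + 3) // 4  # bytes per variant
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bpv:
        raise ValueError(f"{prefix}.bed has {body.size} data bytes, "
                         f"expected {m * bpv}")
    blocks = body.reshape(m, bpv)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    sample_ids = list(zip(fam["fid"], fam["iid"]))
    return RawGenotypes(dosages, sample_ids, bim["snp"].tolist())


def write_plink(raw: RawGenotypes, prefix: str) -> None:
    """Write dosages to a PLINK1 ``.bed/.bim/.fam`` triplet."""
    prefix = str(prefix)
    G = raw.dosages
    n, m = G.shape
    codes = np.full(G.shape, 0b01, dtype=np.uint8)  # missing by default
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[G == dosage] = code
    padded = np.zeros((((n + 3) // 4) * 4, m), dtype=np.uint8)
    padded[:n] = codes
    blocks = padded.T.reshape(m, -1, 4)
    packed = (blocks[:, :, 0] | (blocks[:, :, 1] << 2)
              | (blocks[:, :, 2] << 4) | (blocks[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())
    with open(prefix + ".fam", "w") as fh:
        for sid in raw.sample_ids:
            fid, iid = sid if isinstance(sid, tuple) else (sid, sid)
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for j, vid in enumerate(raw.variant_ids):
            fh.write(f"1 {vid} 0 {j + 1} A G\n")


def read_gcta_grm(prefix: str) -> tuple[np.ndarray, list]:
    """Read a GCTA binary GRM triplet; returns (matrix, sample ids)."""
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if tri.size != expected:
        raise ValueError(f"{prefix}.grm.bin holds {tri.size} float32 values, "
                         f"expected {expected} for {n} samples")
    grm = np.zeros((n, n))
    il, jl = np.tril_indices(n)
    grm[il, jl] = tri
    grm[jl, il] = tri
    return grm, list(zip(ids["fid"], ids["iid"]))


def write_gcta_grm(grm: np.ndarray, sample_ids, prefix: str,
                   n_markers: int | None = None) -> None:
    """Write a dense GRM to the GCTA binary triplet."""
    prefix = str(prefix)
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    il, jl = np.tril_indices(n)
    grm[il, jl].astype("<f4").tofile(prefix + ".grm.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in sample_ids:
            fid, iid = sid if isinstance(sid, tuple) else (sid, sid)
            fh.write(f"{fid}\t{iid}\n")
    if n_markers is not None:
        np.full(il.size, n_markers, dtype="<f4").tofile(prefix + ".grm.N.bin")


def read_pheno_covar(pheno_path: str, covar_path: str | None,
                     sample_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load GCTA-style phenotype/covariate files aligned to genotype order.

    Both files are whitespace-delimited with columns ``FID IID value...``
    and ``NA`` for missing.  Samples are inner-joined on (FID, IID) against
    ``sample_ids``; rows with any missing value are dropped; an intercept
    column is prepended to the covariates.  Returns ``(y, X, kept_index)``
    where ``kept_index`` indexes the genotype samples that survived.
    """
    key = [_as_key(s) for s in sample_ids]
    pheno = _read_table(pheno_path)
    if pheno.shape[1] < 3:
        raise ValueError(f"{pheno_path}: expected columns FID IID phenotype")
    pmap = {(r[0], r[1]): r[2] for r in pheno.itertuples(index=False)}
    cmap = None
    n_cov = 0
    if covar_path is not None:
        covar = _read_table(covar_path)
        if covar.shape[1] < 3:
            raise ValueError(f"{covar_path}: expected columns FID IID covar...")
        n_cov = covar.shape[1] - 2
        cmap = {(r[0], r[1]): r[2:] for r in covar.itertuples(index=False)}
    kept, yvals, xrows = [], [], []
    for i, k in enumerate(key):
        if k not in pmap:
            continue
        pv = pmap[k]
        if cmap is not None and k not in cmap:
            continue
        cv = cmap[k] if cmap is not None else ()
        row = [pv, *cv]
        try:
            row = [float(v) for v in row]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric value for sample {k}") from exc
        if any(np.isnan(v) for v in row):
            continue
        kept.append(i)
        yvals.append(row[0])
        xrows.append(row[1:])
    if not kept:
        raise ValueError("no samples overlap between genotypes and phenotype "
                         "(after removing missing values)")
    dropped = len(key) - len(kept)
    if dropped:
        logger.info("dropped %d of %d genotyped samples (unmatched or missing "
                    "phenotype/covariates)", dropped, len(key))
    y = np.asarray(yvals)
    X = np.column_stack([np.ones(len(kept))]
                        + ([np.asarray(xrows)[:, j] for j in range(n_cov)]))
    return y, X, np.asarray(kept, dtype=int)


def _as_key(sid) -> tuple[str, str]:
    if isinstance(sid, tuple):
        return str(sid[0]), str(sid[1])
    return str(sid), str(sid)


def _read_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     na_values=["NA"], keep_default_na=False)
    out = df.copy()
    out[0] = df[0].astype(str)
    out[1] = df[1].astype(str)
    for j in range(2, df.shape[1]):
        converted = pd.to_numeric(df[j], errors="coerce")
        bad = converted.isna() & df[j].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise ValueError(f"{path}: non-numeric value "
                             f"{df.loc[line - 1, j]!r} at line {line}")
        out[j] = converted
    return out
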