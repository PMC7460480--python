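"""PLINK 1 genotype I/O plus the pipeline's small tabular formats.

Supports the text dialect (.ped/.map) and the binary dialect
(.bed/.bim/.fam, SNP-major, magic bytes 0x6c 0x1b 0x01).  Genotypes are held
as counts of a per-marker "counted" allele — by default the minor allele,
with frequency ties broken by lexicographic allele order — in the range
{0, 1, 2} with -1 as the missing sentinel.  Markers are always kept sorted
by (chrom, bp); positions are 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PlinkParseError",
    "read_plink",
    "write_plink",
    "read_qtl_map",
    "write_qtl_map",
    "read_pheno",
    "write_pheno",
]

MISSING = -1
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x markers counted-allele dosage matrix with a marker map.

    ``markers`` columns: marker, chrom, bp, a1 (counted allele), a2.
    """

    iids: np.ndarray
    genotypes: np.ndarray  # int8, n x m, values {0,1,2,MISSING}
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.iids = np.asarray(self.iids, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.iids) != len(set(self.iids)):
            raise PlinkParseError("duplicate individual ids")
        if self.genotypes.shape != (len(self.iids), len(self.markers)):
            raise PlinkParseError(
                f"genotype matrix {self.genotypes.shape} inconsistent with "
                f"{len(self.iids)} individuals x {len(self.markers)} markers"
            )
        if self.markers["marker"].duplicated().any():
            dup = self.markers.loc[self.markers["marker"].duplicated(), "marker"]
            raise PlinkParseError(f"duplicated marker ids: {list(dup[:5])}")
        order = np.lexsort(
            (self.markers["bp"].to_numpy(), self.markers["chrom"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(self.markers))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]
        else:
            self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.iids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        """Row subset in the order of ``ids`` (all must exist)."""
        index = {iid: i for i, iid in enumerate(self.iids)}
        try:
            rows = np.array([index[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"individual {e} not in genotype matrix") from None
        return GenotypeMatrix(
            iids=np.asarray(list(ids), dtype=object),
            genotypes=self.genotypes[rows],
            markers=self.markers.copy(),
        )

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        index = {m: i for i, m in enumerate(self.markers["marker"])}
        cols = np.array([index[m] for m in marker_ids])
        return GenotypeMatrix(
            iids=self.iids.copy(),
            genotypes=self.genotypes[:, cols],
            markers=self.markers.iloc[cols].reset_index(drop=True),
        )

    def imputed(self) -> np.ndarray:
        """Float matrix with missing genotypes replaced by the marker mean
        (multivariate steps cannot take missing values)."""
        X = self.genotypes.astype(np.float64)
        miss = self.genotypes == MISSING
        if miss.any():
            X[miss] = np.nan
            means = np.nanmean(X, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(miss)
            X[idx] = means[idx[1]]
        return X


# ---------------------------------------------------------------------------
# text dialect


def _pick_counted_allele(a_counts: dict) -> tuple[str, str]:
    """Minor allele (count-ascending, lexicographic tie-break) and the other."""
    alleles = sorted(a_counts)  # lexicographic
    if len(alleles) == 1:
        return alleles[0], "0"
    a, b = alleles
    if a_counts[a] < a_counts[b]:
        return a, b
    if a_counts[b] < a_counts[a]:
        return b, a
    return a, b  # tie at 0.5: lexicographically first is counted


def _read_ped_map(ped_path: str, map_path: str, count: str) -> GenotypeMatrix:
    markers = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise PlinkParseError(f"{map_path}:{ln}: expected 3-4 fields")
            chrom, mid, bp = parts[0], parts[1], parts[-1]
            try:
                bp = int(bp)
            except ValueError:
                raise PlinkParseError(f"{map_path}:{ln}: non-integer bp {bp!r}") from None
            markers.append((chrom, mid, bp))
    m = len(markers)
    iids, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            iids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2) if rows else np.empty(
        (0, m, 2), dtype=object
    )
    geno = np.full((len(rows), m), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        counts: dict = {}
        for a in obs:
            counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise PlinkParseError(
                f"{ped_path}: marker {markers[j][1]} has >2 alleles: {sorted(counts)}"
            )
        if not counts:
            a1s.append("0")
            a2s.append("0")
            continue
        a1, a2 = _pick_counted_allele(counts)
        a1s.append(a1)
        a2s.append(a2)
        valid = (col[:, 0] != "0") & (col[:, 1] != "0")
        geno[valid, j] = (col[valid, 0] == a1).astype(np.int8) + (
            col[valid, 1] == a1
        ).astype(np.int8)
    mk = pd.DataFrame(
        {
            "marker": [x[1] for x in markers],
            "chrom": [_chrom_key(x[0]) for x in markers],
            "bp": [x[2] for x in markers],
            "a1": a1s,
            "a2": a2s,
        }
    )
    return GenotypeMatrix(iids=np.array(iids, dtype=object), genotypes=geno, markers=mk)


def _chrom_key(label: str):
    """Chromosome labels kept as ints when integral, else strings."""
    try:
        return int(label)
    except ValueError:
        return label


# ---------------------------------------------------------------------------
# binary dialect

# 2-bit PLINK codes, counted allele = A1: 00 -> 2 copies, 10 -> 1, 11 -> 0, 01 -> missing
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_bed(prefix: str, count: str) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "marker", "cm", "bp", "a1", "a2"],
        dtype={"a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkParseError(
                f"{prefix}.bed: bad magic {magic!r} (need SNP-major PLINK 1 bed)"
            )
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bpm = (n + 3) // 4
    if len(data) != bpm * m:
        raise PlinkParseError(
            f"{prefix}.bed: {len(data)} payload bytes, expected {bpm * m}"
        )
    data = data.reshape(m, bpm)
    # unpack 2-bit codes, individual-major within byte (LSB first)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bpm * 4)[:, :n]
    geno = _CODE_TO_COUNT[codes].T.copy()  # counts of A1

    a1 = bim["a1"].to_numpy(object)
    a2 = bim["a2"].to_numpy(object)
    if count == "minor":
        valid = geno != MISSING
        with np.errstate(invalid="ignore"):
            s = np.where(valid, geno, 0).sum(axis=0)
            nn = valid.sum(axis=0)
        freq = np.divide(s, 2 * nn, out=np.full(m, np.nan), where=nn > 0)
        flip = freq > 0.5
        tie = freq == 0.5
        lex_flip = tie & (a2 < a1)
        flip = flip | lex_flip
        if flip.any():
            cols = np.flatnonzero(flip)
            g = geno[:, cols]
            g = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
            geno[:, cols] = g
            a1[cols], a2[cols] = a2[cols].copy(), a1[cols].copy()
    elif count != "a1":
        raise ValueError("count must be 'minor' or 'a1'")
    mk = pd.DataFrame(
        {
            "marker": bim["marker"].astype(str),
            "chrom": [_chrom_key(str(c)) for c in bim["chrom"]],
            "bp": bim["bp"].astype(np.int64),
            "a1": a1,
            "a2": a2,
        }
    )
    return GenotypeMatrix(
        iids=fam["iid"].to_numpy(object), genotypes=geno, markers=mk
    )


def read_plink(prefix: str, count: str = "minor") -> GenotypeMatrix:
    """Read a .ped/.map pair or .bed/.bim/.fam triple under ``prefix``.

    ``count='minor'`` (default) codes dosages as minor-allele counts;
    ``count='a1'`` keeps the file's A1 allele as the counted allele (text
    input has no A1 notion, so the flag only affects the binary dialect).
    """
    if os.path.exists(prefix + ".bed"):
        return _read_bed(prefix, count)
    if os.path.exists(prefix + ".ped"):
        return _read_ped_map(prefix + ".ped", prefix + ".map", count)
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped")


def write_plink(
    geno: GenotypeMatrix, prefix: str, binary: bool = False, sex=None, pheno=None
) -> None:
    """Write .ped/.map (default) or .bed/.bim/.fam under ``prefix``."""
    n, m = geno.n_individuals, geno.n_markers
    a1 = geno.markers["a1"].to_numpy(object)
    a2 = geno.markers["a2"].to_numpy(object)
    sex_codes = np.zeros(n, dtype=int) if sex is None else np.where(
        np.asarray(sex) == "M", 1, 2
    )
    phen = np.full(n, -9.0) if pheno is None else np.asarray(pheno, dtype=float)

    if binary:
        with open(prefix + ".bed", "wb") as fh:
            fh.write(_BED_MAGIC)
            bpm = (n + 3) // 4
            codes = np.empty((m, bpm * 4), dtype=np.uint8)
            gt = geno.genotypes.T  # m x n
            code_col = np.select(
                [gt == 2, gt == 1, gt == 0], [0b00, 0b10, 0b11], default=0b01
            ).astype(np.uint8)
            codes[:, :n] = code_col
            codes[:, n:] = 0b01  # pad slots are "missing"
            packed = (
                codes.reshape(m, bpm, 4)
                << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
            ).sum(axis=2, dtype=np.uint16).astype(np.uint8)
            fh.write(packed.tobytes())
        with open(prefix + ".bim", "w") as fh:
            for j, row in geno.markers.iterrows():
                fh.write(
                    f"{row['chrom']}\t{row['marker']}\t0\t{row['bp']}\t{a1[j]}\t{a2[j]}\n"
                )
        with open(prefix + ".fam", "w") as fh:
            for i, iid in enumerate(geno.iids):
                fh.write(f"{iid} {iid} 0 0 {sex_codes[i]} {phen[i]}\n")
        return

    with open(prefix + ".map", "w") as fh:
        for _, row in geno.markers.iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t0\t{row['bp']}\n")
    pair = {
        2: [a1, a1],
        1: [a1, a2],
        0: [a2, a2],
    }
    with open(prefix + ".ped", "w") as fh:
        for i, iid in enumerate(geno.iids):
            fields = [str(iid), str(iid), "0", "0", str(sex_codes[i]), str(phen[i])]
            g = geno.genotypes[i]
            for j in range(m):
                if g[j] == MISSING:
                    fields.extend(["0", "0"])
                else:
                    x, y = pair[int(g[j])]
                    fields.extend([str(x[j]), str(y[j])])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# tabular side files (TSV with header, 1-based positions)


def read_qtl_map(path: str) -> pd.DataFrame:
    """QTL map TSV (`chrom  bp  effect`), returned sorted by (chrom, bp)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "bp", "effect"}
    if not required.issubset(df.columns):
        raise PlinkParseError(f"{path}: need columns {sorted(required)}")
    try:
        df["bp"] = df["bp"].astype(np.int64)
        df["effect"] = df["effect"].astype(float)
    except (ValueError, TypeError) as e:
        raise PlinkParseError(f"{path}: non-numeric bp or effect ({e})") from None
    df["chrom"] = [_chrom_key(str(c)) for c in df["chrom"]]
    return df.sort_values(["chrom", "bp"], kind="mergesort").reset_index(drop=True)


def write_qtl_map(qtls: pd.DataFrame, path: str) -> None:
    qtls[["chrom", "bp", "effect"]].to_csv(path, sep="\t", index=False)


def read_pheno(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise PlinkParseError(f"{path}: phenotype table needs an 'id' column")
    return df


def write_pheno(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)
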