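"""Genotype, map and metadata I/O plus marker/genotype quality control.

Genotypes are held as an accession x marker matrix of additive codes
(0 = homozygous reference allele, 1 = heterozygous, 2 = homozygous
alternate, -1 = missing) together with the recorded allele letters per
marker.  Two text dialects are supported: a plain ``matrix_tsv`` (header
row of marker ids, first column accession id, calls 0/1/2/NA) that
round-trips bit-exactly, and a HapMap-like tab format with the standard
eleven leading columns and diploid letter calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
_VALID_CODES = frozenset({0, 1, 2, MISSING})

#: HapMap leading columns tolerated before the accession columns start.
HAPMAP_LEADING = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class ParseError(ValueError):
    """Malformed genotype/map file; message names the offending line."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a panel of accessions.

    Parameters
    ----------
    accession_ids : ordered unique accession labels (rows).
    marker_ids : ordered unique marker labels (columns).
    calls : int8 array, shape (n_accessions, n_markers), values in
        {0, 1, 2, -1} with -1 encoding a missing call.
    alleles : per-marker (ref_letter, alt_letter) pairs; code 0 counts two
        copies of the ref letter.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        if not self.alleles:
            self.alleles = [("A", "B")] * len(self.marker_ids)
        if len(self.alleles) != len(self.marker_ids):
            raise ValueError("alleles length inconsistent with marker count")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_missingness(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def accession_missingness(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker from allele counts over
        non-missing calls (2 per homozygote, 1 per heterozygote).
        Monomorphic-in-missing markers get MAF 0."""
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        return np.where(np.isnan(maf), 0.0, maf)

    def dosage(self, impute: bool = True) -> np.ndarray:
        """Float copy of the calls with missing entries mean-imputed per
        marker (used for kinship/PCA/association, never stored back)."""
        x = self.calls.astype(float)
        x[x == MISSING] = np.nan
        if impute:
            col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def subset(self, accessions: Sequence[str] | None = None,
               markers: Sequence[str] | None = None) -> "GenotypeMatrix":
        acc = list(accessions) if accessions is not None else self.accession_ids
        mk = list(markers) if markers is not None else self.marker_ids
        ai = [self.accession_ids.index(a) for a in acc]
        mi = [self.marker_ids.index(m) for m in mk]
        return GenotypeMatrix(
            accession_ids=acc,
            marker_ids=mk,
            calls=self.calls[np.ix_(ai, mi)].copy(),
            alleles=[self.alleles[i] for i in mi],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and self.alleles == other.alleles
        )


# ---------------------------------------------------------------------------
# marker map

MAP_COLUMNS = ["marker", "chrom", "cm", "bp"]

WHEAT_CHROMOSOMES = [f"{n}{g}" for n in range(1, 8) for g in "ABD"]


def make_marker_map(marker: Sequence[str], chrom: Sequence[str],
                    cm: Sequence[float], bp: Sequence[float] | None = None) -> pd.DataFrame:
    """Assemble a marker map frame (columns marker, chrom, cm, bp).

    bp may contain NaN for markers without a physical position.
    """
    df = pd.DataFrame({
        "marker": list(marker),
        "chrom": list(chrom),
        "cm": np.asarray(cm, dtype=float),
        "bp": np.full(len(marker), np.nan) if bp is None else np.asarray(bp, dtype=float),
    })
    if (df["cm"] < 0).any():
        raise ValueError("negative cM position in marker map")
    present = df["bp"].notna()
    if (df.loc[present, "bp"] < 1).any():
        raise ValueError("bp positions are 1-based; found bp < 1")
    return df


def read_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"map file {path} lacks columns {missing}")
    return make_marker_map(df["marker"], df["chrom"], df["cm"], df["bp"])


def write_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    marker_map.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# genotype file formats

def read_genotypes(path: str | Path, format: str = "matrix_tsv"):
    """Read genotypes; returns (GenotypeMatrix, MarkerMap or None).

    ``matrix_tsv`` carries no positional or allele information (map is
    None, alleles default to A/B); the HapMap dialect returns a map built
    from its chrom/pos columns (cM unknown, set to NaN... the genetic map
    is supplied separately via :func:`read_map`).
    """
    if format == "matrix_tsv":
        return _read_matrix_tsv(path), None
    if format == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str = "matrix_tsv") -> None:
    if format == "matrix_tsv":
        _write_matrix_tsv(G, path)
    elif format == "hapmap":
        _write_hapmap(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header must list marker ids")
        marker_ids = header[1:]
        accession_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            accession_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:], start=2):
                if tok == "NA":
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise ParseError(f"{path}:{lineno}: invalid call {tok!r}")
            rows.append(row)
    return GenotypeMatrix(accession_ids, marker_ids, np.array(rows, dtype=np.int8))


def _write_matrix_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("accession\t" + "\t".join(G.marker_ids) + "\n")
        for i, acc in enumerate(G.accession_ids):
            toks = ["NA" if c == MISSING else str(int(c)) for c in G.calls[i]]
            fh.write(acc + "\t" + "\t".join(toks) + "\n")


def _decode_hapmap_call(tok: str, ref: str, alt: str, where: str) -> int:
    if tok in ("NN", "N", "--"):
        return MISSING
    if len(tok) == 1:  # haploid-style shorthand
        tok = tok + tok
    if len(tok) != 2:
        raise ParseError(f"{where}: invalid genotype call {tok!r}")
    n_alt = 0
    for letter in tok:
        if letter == alt:
            n_alt += 1
        elif letter != ref:
            raise ParseError(
                f"{where}: call {tok!r} has allele {letter!r} not in {ref}/{alt}")
    return n_alt


def _read_hapmap(path: str | Path):
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < len(HAPMAP_LEADING) + 1:
            raise ParseError(f"{path}:1: too few columns for a HapMap file")
        accession_ids = header[len(HAPMAP_LEADING):]
        marker_ids: list[str] = []
        chroms: list[str] = []
        bps: list[float] = []
        alleles: list[tuple[str, str]] = []
        cols: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            marker_ids.append(parts[0])
            try:
                ref, alt = parts[1].split("/")
            except ValueError:
                raise ParseError(f"{path}:{lineno}: alleles field {parts[1]!r}") from None
            chroms.append(parts[2])
            bps.append(float(parts[3]))
            alleles.append((ref, alt))
            cols.append([
                _decode_hapmap_call(tok, ref, alt, f"{path}:{lineno}")
                for tok in parts[len(HAPMAP_LEADING):]
            ])
    calls = np.array(cols, dtype=np.int8).T
    G = GenotypeMatrix(accession_ids, marker_ids, calls, alleles)
    mmap = make_marker_map(marker_ids, chroms, [np.nan] * len(marker_ids), bps)
    return G, mmap


def _write_hapmap(G: GenotypeMatrix, path: str | Path,
                  marker_map: pd.DataFrame | None = None) -> None:
    pos = {}
    if marker_map is not None:
        pos = dict(zip(marker_map["marker"], zip(marker_map["chrom"], marker_map["bp"])))
    with Path(path).open("w") as fh:
        fh.write("\t".join(HAPMAP_LEADING + list(G.accession_ids)) + "\n")
        for j, mk in enumerate(G.marker_ids):
            ref, alt = G.alleles[j]
            chrom, bp = pos.get(mk, ("NA", 0))
            lead = [mk, f"{ref}/{alt}", str(chrom), str(int(bp) if bp == bp else 0),
                    "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            geno = []
            for c in G.calls[:, j]:
                if c == MISSING:
                    geno.append("NN")
                else:
                    geno.append({0: ref + ref, 1: ref + alt, 2: alt + alt}[int(c)])
            fh.write("\t".join(lead + geno) + "\n")


# ---------------------------------------------------------------------------
# quality control

@dataclass
class QcConfig:
    """Marker/genotype filtering thresholds.

    Defaults follow the study's pipeline: drop accessions and markers above
    25% missing data, markers below 5% minor allele frequency, and all but
    one representative of each duplicated call pattern.
    """

    max_marker_missing: float = 0.25
    min_maf: float = 0.05
    drop_duplicate_patterns: bool = True
    max_accession_missing: float = 0.25

    def __post_init__(self) -> None:
        for name in ("max_marker_missing", "min_maf", "max_accession_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_accessions_in: int
    n_markers_in: int
    accessions_removed_missing: list[str]
    markers_removed_duplicate: list[str]
    markers_removed_missing: list[str]
    markers_removed_maf: list[str]

    @property
    def n_accessions_out(self) -> int:
        return self.n_accessions_in - len(self.accessions_removed_missing)

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - len(self.markers_removed_duplicate) \
            - len(self.markers_removed_missing) - len(self.markers_removed_maf)

    def to_frame(self) -> pd.DataFrame:
        rows = [("accession_missingness", a) for a in self.accessions_removed_missing]
        rows += [("duplicate_pattern", m) for m in self.markers_removed_duplicate]
        rows += [("marker_missingness", m) for m in self.markers_removed_missing]
        rows += [("maf", m) for m in self.markers_removed_maf]
        return pd.DataFrame(rows, columns=["rule", "id"])


def qc_filter(G: GenotypeMatrix, cfg: QcConfig | None = None):
    """Apply the QC cascade; returns (filtered GenotypeMatrix, QcReport).

    Fixed order: accessions above the missingness cap are dropped first,
    then duplicate call patterns (first occurrence in input order kept),
    then marker missingness, then MAF — each stage computed on the output
    of the previous one.  The operation is idempotent.
    """
    cfg = cfg or QcConfig()
    report_kwargs = dict(n_accessions_in=G.n_accessions, n_markers_in=G.n_markers)

    acc_keep = G.accession_missingness() <= cfg.max_accession_missing
    removed_acc = [a for a, k in zip(G.accession_ids, acc_keep) if not k]
    if removed_acc:
        G = G.subset(accessions=[a for a, k in zip(G.accession_ids, acc_keep) if k])

    marker_keep = np.ones(G.n_markers, dtype=bool)
    dup_removed: list[str] = []
    if cfg.drop_duplicate_patterns:
        seen: dict[bytes, int] = {}
        for j in range(G.n_markers):
            key = G.calls[:, j].tobytes()
            if key in seen:
                marker_keep[j] = False
                dup_removed.append(G.marker_ids[j])
            else:
                seen[key] = j

    miss = G.marker_missingness()
    miss_removed = [G.marker_ids[j] for j in range(G.n_markers)
                    if marker_keep[j] and miss[j] > cfg.max_marker_missing]
    marker_keep &= miss <= cfg.max_marker_missing

    maf = G.maf()
    maf_removed = [G.marker_ids[j] for j in range(G.n_markers)
                   if marker_keep[j] and maf[j] < cfg.min_maf]
    marker_keep &= maf >= cfg.min_maf

    kept_markers = [m for m, k in zip(G.marker_ids, marker_keep) if k]
    out = G.subset(markers=kept_markers)
    if out.n_markers == 0:
        warnings.warn("qc_filter removed every marker", stacklevel=2)
    report = QcReport(
        accessions_removed_missing=removed_acc,
        markers_removed_duplicate=dup_removed,
        markers_removed_missing=miss_removed,
        markers_removed_maf=maf_removed,
        **report_kwargs,
    )
    return out, report


# ---------------------------------------------------------------------------
# group allele frequencies

def group_allele_frequencies(G: GenotypeMatrix, groups: Mapping[str, str],
                             marker_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Allele frequencies per marker x group over non-missing calls.

    ``groups`` maps accession id -> group label; every accession in G must
    be labelled.  Returns a long frame (marker, group, allele, frequency,
    defined); a group with zero non-missing calls at a marker is flagged
    defined=False with NaN frequencies.  Defined frequencies of the two
    recorded alleles sum to 1 per marker x group.
    """
    unlabelled = [a for a in G.accession_ids if a not in groups]
    if unlabelled:
        raise ValueError(f"accessions without a group label: {unlabelled[:5]}")
    marker_ids = list(marker_ids) if marker_ids is not None else G.marker_ids
    mk_index = {m: j for j, m in enumerate(G.marker_ids)}
    unknown = [m for m in marker_ids if m not in mk_index]
    if unknown:
        raise ValueError(f"unknown markers: {unknown[:5]}")

    labels = np.array([groups[a] for a in G.accession_ids])
    rows = []
    for g in pd.unique(labels):
        sel = labels == g
        calls = G.calls[sel]
        for m in marker_ids:
            j = mk_index[m]
            c = calls[:, j]
            obs = c != MISSING
            n = 2 * int(obs.sum())
            ref, alt = G.alleles[j]
            if n == 0:
                rows.append((m, g, ref, np.nan, False))
                rows.append((m, g, alt, np.nan, False))
                continue
            alt_count = int(c[obs].sum())
            rows.append((m, g, ref, (n - alt_count) / n, True))
            rows.append((m, g, alt, alt_count / n, True))
    return pd.DataFrame(rows, columns=["marker", "group", "allele", "frequency", "defined"])
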