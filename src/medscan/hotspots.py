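"""QTL-hotspot consolidation from marker-trait associations.

Each association is standardised into a Gaussian position density whose
standard deviation derives from the chromosome's LD-decay extent CI (in
cM): sigma = CI / 3.92, the 95% interval width convention (3.92 =
2 x 1.96).  The per-cM *overview index* U(x) sums these densities over
all associations and divides by the number of experiments nbE (trait-scan
combinations), so integral U dx = nbQTL / nbE.  Positions where U exceeds
a threshold form runs; each run contributes a peak at its argmax.  The
mean threshold is the average density nbQTL / (nbE x map length) and the
high threshold a configurable multiple of it (default 5).

Peaks close on the genetic map (intervals peak +- CI/2 overlapping) merge
into named hotspots (1A.1, 1A.2, ... per chromosome in cM order); each
hotspot is then given flanking mapped markers, a physical bp interval and
its width in Mb; hotspots wider than 20 Mb are dropped from candidate-gene
search and same-chromosome hotspots with intersecting bp intervals are
fused (names concatenate ordinals, e.g. 1B.1-2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import Mta

#: 2 x 1.96 — width of the central 95% mass of a Gaussian in sd units.
GAUSSIAN_95_WIDTH = 3.92


def mta_sigma(ld_ci_cm: float) -> float:
    """Gaussian sd (cM) of one association's position density: CI / 3.92."""
    if ld_ci_cm <= 0:
        raise ValueError(f"LD confidence interval must be positive, got {ld_ci_cm}")
    return ld_ci_cm / GAUSSIAN_95_WIDTH


@dataclass
class OverviewProfile:
    positions: dict[str, np.ndarray]   # integer-cM grid per chromosome
    u: dict[str, np.ndarray]           # overview index per grid point
    nb_qtl: int
    nb_e: int
    map_length_cm: float
    mean_threshold: float
    high_threshold: float

    def total_mass(self) -> float:
        """Integral of U over the grid (1-cM spacing) — approximately
        nbQTL/nbE when no density mass spills past chromosome ends."""
        return float(sum(arr.sum() for arr in self.u.values()))

    def to_frame(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"chrom": c, "cm": self.positions[c], "u": self.u[c]})
                  for c in self.positions]
        return pd.concat(frames, ignore_index=True)


@dataclass
class Peak:
    chrom: str
    position: int          # argmax of the run (leftmost on ties)
    height: float
    run_start: int
    run_end: int           # inclusive
    n_positions: int


@dataclass
class Hotspot:
    name: str
    chromosome: str
    cm_interval: tuple[float, float]
    trait_classes: set[str] = field(default_factory=set)
    left_marker: str | None = None
    right_marker: str | None = None
    bp_interval: tuple[float, float] | None = None
    ci_mb: float | None = None
    n_gene_models: int | None = None

    @property
    def genome(self) -> str:
        """Genome letter (A/B/D) — last character of the chromosome label."""
        return self.chromosome[-1]


def overview_index(mtas: Sequence[Mta], marker_map: pd.DataFrame,
                   ld_ci: Mapping[str, float], nb_e: int,
                   high_multiplier: float = 5.0,
                   chrom_lengths: Mapping[str, float] | None = None) -> OverviewProfile:
    """Per-cM overview index over all chromosomes of the map.

    U(x) = (1/nbE) sum_q Normal(x; cm_q, sigma_chrom^2) on the integer-cM
    grid [0, chromosome length]; mean threshold nbQTL/(nbE * map length),
    high threshold ``high_multiplier`` times that.
    """
    if nb_e < 1:
        raise ValueError("nb_e must be >= 1")
    if chrom_lengths is None:
        chrom_lengths = marker_map.groupby("chrom")["cm"].max().to_dict()
    total_length = float(sum(chrom_lengths.values()))
    positions, u = {}, {}
    for chrom, length in chrom_lengths.items():
        grid = np.arange(0, int(math.floor(length)) + 1)
        positions[chrom] = grid
        u[chrom] = np.zeros(len(grid), dtype=float)

    n_qtl = 0
    for m in mtas:
        if m.cm is None or m.chromosome is None:
            raise ValueError(f"association at {m.marker_id} lacks a map position")
        if m.chromosome not in positions:
            continue
        sigma = mta_sigma(float(ld_ci[m.chromosome]))
        grid = positions[m.chromosome]
        u[m.chromosome] += np.exp(-0.5 * ((grid - m.cm) / sigma) ** 2) \
            / (sigma * math.sqrt(2.0 * math.pi))
        n_qtl += 1
    for chrom in u:
        u[chrom] /= nb_e

    if n_qtl == 0:
        warnings.warn("no associations: overview profile is all zero", stacklevel=2)
        mean_thr = 0.0
    else:
        mean_thr = n_qtl / (nb_e * total_length)
    return OverviewProfile(
        positions=positions, u=u, nb_qtl=n_qtl, nb_e=nb_e,
        map_length_cm=total_length, mean_threshold=mean_thr,
        high_threshold=high_multiplier * mean_thr)


def detect_peaks(profile: OverviewProfile, threshold: float):
    """Runs of consecutive integer-cM positions with U > threshold.

    Returns (peaks, n_positions): one peak per maximal run, placed at the
    run's argmax (leftmost on ties); n_positions counts all grid points
    above the threshold.
    """
    peaks: list[Peak] = []
    n_positions = 0
    for chrom, grid in profile.positions.items():
        vals = profile.u[chrom]
        above = vals > threshold
        n_positions += int(above.sum())
        i = 0
        while i < len(grid):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grid) and above[j + 1]:
                j += 1
            seg = vals[i:j + 1]
            arg = i + int(np.argmax(seg))
            peaks.append(Peak(chrom=chrom, position=int(grid[arg]),
                              height=float(vals[arg]), run_start=int(grid[i]),
                              run_end=int(grid[j]), n_positions=j - i + 1))
            i = j + 1
    return peaks, n_positions


def _nearest_mapped_marker(chrom_map: pd.DataFrame, cm_target: float):
    mapped = chrom_map[chrom_map["bp"].notna()]
    if mapped.empty:
        return None, None
    idx = (mapped["cm"] - cm_target).abs().idxmin()
    return str(mapped.loc[idx, "marker"]), float(mapped.loc[idx, "bp"])


def build_hotspots(peaks: Sequence[Peak], profile: OverviewProfile,
                   ld_ci: Mapping[str, float], marker_map: pd.DataFrame,
                   mtas: Sequence[Mta]) -> list[Hotspot]:
    """Merge nearby peaks into named hotspots and attach flanking markers.

    Peaks on one chromosome whose intervals peak +- CI/2 overlap are
    merged; the hotspot cM interval is the union of the merged peak
    intervals clipped to the chromosome.  Trait classes collect from the
    associations falling inside the interval; flanking markers are the
    mapped (bp-bearing) markers nearest each interval end.  Hotspots
    without any bp-mapped marker keep ``bp_interval=None`` (flagged by a
    warning) and are later excluded from physical selection.
    """
    hotspots: list[Hotspot] = []
    mta_frame = pd.DataFrame(
        [(m.chromosome, m.cm, m.trait_class) for m in mtas],
        columns=["chrom", "cm", "trait_class"])
    for chrom in profile.positions:
        chrom_peaks = sorted([p for p in peaks if p.chrom == chrom],
                             key=lambda p: p.position)
        if not chrom_peaks:
            continue
        half = float(ld_ci[chrom]) / 2.0
        clusters: list[list[Peak]] = []
        for p in chrom_peaks:
            if clusters and p.position - half <= clusters[-1][-1].position + half:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        chrom_map = marker_map[marker_map["chrom"] == chrom]
        chrom_mtas = mta_frame[mta_frame["chrom"] == chrom]
        length = float(profile.positions[chrom][-1])
        for ordinal, cluster in enumerate(clusters, start=1):
            lo = max(min(p.position - half for p in cluster), 0.0)
            hi = min(max(p.position + half for p in cluster), length)
            classes = set(chrom_mtas.loc[
                (chrom_mtas["cm"] >= lo) & (chrom_mtas["cm"] <= hi), "trait_class"])
            h = Hotspot(name=f"{chrom}.{ordinal}", chromosome=chrom,
                        cm_interval=(lo, hi), trait_classes=classes)
            left_mk, left_bp = _nearest_mapped_marker(chrom_map, lo)
            right_mk, right_bp = _nearest_mapped_marker(chrom_map, hi)
            if left_mk is None:
                warnings.warn(f"hotspot {h.name}: no bp-mapped marker on {chrom}",
                              stacklevel=2)
            else:
                h.left_marker, h.right_marker = left_mk, right_mk
                h.bp_interval = (left_bp, right_bp)
                h = physical_interval(h)
            hotspots.append(h)
    return hotspots


def physical_interval(h: Hotspot) -> Hotspot:
    """Sort the bp interval and fill ci_mb = |right - left| / 1e6 (2 dp)."""
    if h.bp_interval is None or h.left_marker is None:
        warnings.warn(f"hotspot {h.name} lacks physical positions", stacklevel=2)
        return h
    a, b = h.bp_interval
    if b < a:
        a, b = b, a
        h.left_marker, h.right_marker = h.right_marker, h.left_marker
    h.bp_interval = (a, b)
    h.ci_mb = round((b - a) / 1.0e6, 2)
    return h


def select_hotspots(hs: Sequence[Hotspot], max_ci_mb: float = 20.0) -> list[Hotspot]:
    """Retain hotspots with a physical CI no wider than ``max_ci_mb`` Mb.

    Hotspots without a bp interval are excluded (cannot be searched for
    genes).  Use :func:`genome_counts` for the per-genome tally.
    """
    return [h for h in hs if h.ci_mb is not None and h.ci_mb <= max_ci_mb]


def genome_counts(hs: Sequence[Hotspot]) -> dict[str, int]:
    out: dict[str, int] = {}
    for h in hs:
        out[h.genome] = out.get(h.genome, 0) + 1
    return out


def merge_overlapping(hs: Sequence[Hotspot]) -> list[Hotspot]:
    """Fuse same-chromosome hotspots whose bp intervals intersect.

    Intersection is inclusive; adjacent-but-disjoint intervals (gap of at
    least 1 bp) stay separate.  A merged hotspot unions the intervals and
    trait classes and concatenates the ordinals in its name (1B.1-2).
    """
    by_chrom: dict[str, list[Hotspot]] = {}
    passthrough: list[Hotspot] = []
    for h in hs:
        if h.bp_interval is None:
            passthrough.append(h)
        else:
            by_chrom.setdefault(h.chromosome, []).append(h)
    merged: list[Hotspot] = []
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda h: h.bp_interval[0])
        current = [items[0]]
        reach = items[0].bp_interval[1]
        for h in items[1:]:
            if h.bp_interval[0] <= reach:
                current.append(h)
                reach = max(reach, h.bp_interval[1])
            else:
                merged.append(_fuse(current))
                current, reach = [h], h.bp_interval[1]
        merged.append(_fuse(current))
    return merged + passthrough


def _ordinal(name: str) -> str:
    return name.split(".", 1)[1] if "." in name else name


def _fuse(group: list[Hotspot]) -> Hotspot:
    if len(group) == 1:
        return group[0]
    group = sorted(group, key=lambda h: _ordinal(h.name))
    lo = min(h.bp_interval[0] for h in group)
    hi = max(h.bp_interval[1] for h in group)
    left = min(group, key=lambda h: h.bp_interval[0])
    right = max(group, key=lambda h: h.bp_interval[1])
    name = f"{group[0].chromosome}." + "-".join(_ordinal(h.name) for h in group)
    fused = Hotspot(
        name=name, chromosome=group[0].chromosome,
        cm_interval=(min(h.cm_interval[0] for h in group),
                     max(h.cm_interval[1] for h in group)),
        trait_classes=set().union(*(h.trait_classes for h in group)),
        left_marker=left.left_marker, right_marker=right.right_marker,
        bp_interval=(lo, hi))
    return physical_interval(fused)


def hotspots_to_frame(hs: Sequence[Hotspot]) -> pd.DataFrame:
    rows = []
    for h in hs:
        rows.append({
            "hotspot": h.name, "chrom": h.chromosome,
            "cm_start": h.cm_interval[0], "cm_end": h.cm_interval[1],
            "trait_classes": ",".join(sorted(h.trait_classes)),
            "left_marker": h.left_marker, "right_marker": h.right_marker,
            "bp_start": None if h.bp_interval is None else h.bp_interval[0],
            "bp_end": None if h.bp_interval is None else h.bp_interval[1],
            "ci_mb": h.ci_mb, "n_gene_models": h.n_gene_models,
        })
    return pd.DataFrame(rows)


def hotspots_from_frame(df: pd.DataFrame) -> list[Hotspot]:
    """Rebuild Hotspot objects from a report frame (or the packaged
    reference table, which uses left_bp/right_bp in printed order)."""
    out = []
    for _, r in df.iterrows():
        if {"left_bp", "right_bp"} <= set(df.columns):
            interval = (float(r["left_bp"]), float(r["right_bp"]))
        else:
            interval = (float(r["bp_start"]), float(r["bp_end"]))
        h = Hotspot(
            name=str(r["hotspot"]), chromosome=str(r["chrom"]),
            cm_interval=(float(r["cm_start"]), float(r["cm_end"])),
            trait_classes=set(str(r["trait_classes"]).split(","))
            if pd.notna(r.get("trait_classes")) else set(),
            left_marker=r.get("left_marker"), right_marker=r.get("right_marker"),
            bp_interval=interval,
            n_gene_models=int(r["n_gene_models"]) if pd.notna(r.get("n_gene_models"))
            else None)
        out.append(h)
    return out
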