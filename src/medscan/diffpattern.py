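"""Subpopulation allele-frequency differentiation within hotspots.

A marker discriminates two subpopulations when their majority alleles
differ; the strength of the call depends on how fixed each majority
allele is.  Both majority frequencies at or above 80% is a *robust*
difference; both at or above 60% (but not robust) is *moderate*;
anything else is *none*.  The classification is symmetric in the pair
and invariant to swapping allele labels.  Admixed accessions carry no
clean subpopulation label and should be excluded upstream when the
frequency table is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence
import warnings

import numpy as np
import pandas as pd


@dataclass
class DiffConfig:
    robust_threshold: float = 0.80
    moderate_threshold: float = 0.60

    def __post_init__(self) -> None:
        if not 0.5 < self.moderate_threshold < self.robust_threshold <= 1.0:
            raise ValueError(
                "need 0.5 < moderate_threshold < robust_threshold <= 1")


@dataclass
class DiffPattern:
    hotspot: str | None
    marker: str
    subpop_a: str
    subpop_b: str
    allele_a: str            # majority allele in subpop_a
    freq_a: float
    allele_b: str
    freq_b: float
    classification: str      # robust | moderate | none


def _majorities(freqs: pd.DataFrame):
    """Majority allele + frequency per (marker, group); ties resolved by
    allele letter for reproducibility."""
    f = freqs.sort_values(["frequency", "allele"], ascending=[False, True],
                          kind="stable")
    top = f.groupby(["marker", "group"], sort=False).first().reset_index()
    return top


def classify_differentiation(freqs: pd.DataFrame,
                             cfg: DiffConfig | None = None,
                             hotspot_of: dict[str, str] | None = None) -> list[DiffPattern]:
    """Classify every subpopulation pair at every marker of a frequency table.

    ``freqs`` is long (marker, group, allele, frequency[, defined]) as
    produced by :func:`medscan.genio.group_allele_frequencies` or loaded
    from a published table.  Markers with an undefined (empty-group)
    frequency are skipped with a warning.
    """
    cfg = cfg or DiffConfig()
    freqs = freqs.copy()
    if "group" not in freqs.columns and "subpop" in freqs.columns:
        freqs = freqs.rename(columns={"subpop": "group"})
    if hotspot_of is None and "hotspot" in freqs.columns:
        hotspot_of = dict(zip(freqs["marker"], freqs["hotspot"]))
    if "defined" in freqs.columns:
        bad = freqs.loc[~freqs["defined"].astype(bool) |
                        freqs["frequency"].isna(), "marker"].unique()
    else:
        bad = freqs.loc[freqs["frequency"].isna(), "marker"].unique()
    if len(bad):
        warnings.warn(f"skipping markers with undefined frequencies: {list(bad)}",
                      stacklevel=2)
        freqs = freqs[~freqs["marker"].isin(bad)]

    top = _majorities(freqs)
    out: list[DiffPattern] = []
    for marker, sub in top.groupby("marker", sort=False):
        sub = sub.sort_values("group", kind="stable")
        for (_, a), (_, b) in combinations(sub.iterrows(), 2):
            if a["allele"] != b["allele"]:
                lo = min(a["frequency"], b["frequency"])
                if lo >= cfg.robust_threshold:
                    label = "robust"
                elif lo >= cfg.moderate_threshold:
                    label = "moderate"
                else:
                    label = "none"
            else:
                label = "none"
            out.append(DiffPattern(
                hotspot=(hotspot_of or {}).get(marker),
                marker=str(marker),
                subpop_a=str(a["group"]), subpop_b=str(b["group"]),
                allele_a=str(a["allele"]), freq_a=float(a["frequency"]),
                allele_b=str(b["allele"]), freq_b=float(b["frequency"]),
                classification=label))
    return out


def patterns_to_frame(patterns: Sequence[DiffPattern]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in patterns])


_RANK = {"none": 0, "moderate": 1, "robust": 2}


def hotspot_diff_summary(patterns: Sequence[DiffPattern],
                         hotspot_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-hotspot roll-up: strongest classification over its markers and
    the subpopulation pairs discriminated at that strength."""
    df = patterns_to_frame(patterns) if patterns else pd.DataFrame(
        columns=["hotspot", "marker", "subpop_a", "subpop_b", "classification"])
    rows = []
    names = hotspot_names if hotspot_names is not None else \
        [h for h in df["hotspot"].dropna().unique()]
    for name in names:
        sub = df[df["hotspot"] == name]
        if sub.empty:
            rows.append((name, "none", ""))
            continue
        best = sub["classification"].map(_RANK).max()
        label = {v: k for k, v in _RANK.items()}[best]
        pairs = sorted({f"{a}-{b}" for a, b, c in
                        zip(sub["subpop_a"], sub["subpop_b"], sub["classification"])
                        if _RANK[c] == best and best > 0})
        rows.append((name, label, ";".join(pairs)))
    return pd.DataFrame(rows, columns=["hotspot", "classification", "pairs"])
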