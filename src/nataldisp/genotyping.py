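"""Microsatellite identity matching and probability-of-identity statistics.

Individuals are identified by comparing multilocus microsatellite genotypes of
breeding adults (typically from moulted feathers collected at nests) against a
reference set of nestling genotypes.  Two samples are declared the same
individual when their genotypes agree at every mutually typed locus, a missing
locus acting as a wildcard, provided enough loci overlap.  Samples typed at
fewer than ``min_typed`` loci (default 9) are removed before screening, and an
adult profile matching more than one distinct nestling is flagged ambiguous
and excluded from linkage.

The reliability of a locus panel for identification is summarised by the
probability of identity: the chance that two individuals drawn at random from
a population in Hardy-Weinberg equilibrium share a genotype, computed per
locus from allele frequencies and multiplied across independent loci.  The
sibling variant conditions on the two individuals being full sibs and is the
conservative bound used in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "LocusDef",
    "MultilocusGenotype",
    "MatchResult",
    "match_pair",
    "screen",
    "pid_locus",
    "pid_sib_locus",
    "pid_combined",
    "calibrate_datasets",
    "genotypes_from_frame",
    "locus_columns",
]


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus with its population allele frequencies."""

    name: str
    allele_frequencies: Mapping[int, float]

    def __post_init__(self):
        freqs = np.asarray(list(self.allele_frequencies.values()), dtype=float)
        if freqs.size < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele")
        if np.any(freqs < 0):
            raise ValueError(f"locus {self.name}: negative allele frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name}: frequencies sum to {freqs.sum():.6g}, not 1")


@dataclass(frozen=True)
class MultilocusGenotype:
    """One sample's multilocus genotype.

    ``calls`` maps locus name to an unordered allele-size pair (stored
    sorted) or None for missing.  The key set of ``calls`` defines the locus
    panel the sample was assayed for.
    """

    sample_id: str
    calls: Mapping[str, tuple[int, int] | None]
    sex_call: str = "UNKNOWN"
    individual_hint: str | None = None

    def __post_init__(self):
        fixed = {}
        for locus, pair in self.calls.items():
            if pair is None:
                fixed[locus] = None
            else:
                a, b = int(pair[0]), int(pair[1])
                fixed[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "calls", fixed)
        if self.sex_call not in {"F", "M", "UNKNOWN"}:
            raise ValueError(f"bad sex call {self.sex_call!r}")

    @property
    def n_typed(self) -> int:
        return sum(1 for v in self.calls.values() if v is not None)


@dataclass(frozen=True)
class MatchResult:
    nestling_sample: str
    adult_sample: str
    n_compared: int
    n_mismatch: int
    decision: str  # MATCH | NO_MATCH | INSUFFICIENT_OVERLAP


def match_pair(a: MultilocusGenotype, b: MultilocusGenotype,
               min_overlap: int = 9, max_mismatch: int = 0) -> MatchResult:
    """Compare two genotypes locus by locus over their shared panel.

    A locus contributes to the comparison only when typed in both samples;
    a missing call on either side matches anything.  A typed-locus comparison
    mismatches iff the unordered allele pairs differ (multiset comparison, so
    a homozygote never part-matches a heterozygote).
    """
    shared = set(a.calls) & set(b.calls)
    if not shared:
        raise ValueError(f"genotypes {a.sample_id} and {b.sample_id} share no loci")
    n_compared = 0
    n_mismatch = 0
    for locus in shared:
        pa, pb = a.calls[locus], b.calls[locus]
        if pa is None or pb is None:
            continue
        n_compared += 1
        if pa != pb:
            n_mismatch += 1
    if n_compared < min_overlap:
        decision = "INSUFFICIENT_OVERLAP"
    elif n_mismatch <= max_mismatch:
        decision = "MATCH"
    else:
        decision = "NO_MATCH"
    return MatchResult(a.sample_id, b.sample_id, n_compared, n_mismatch, decision)


# ---------------------------------------------------------------------------
# table-level screening


def locus_columns(df: pd.DataFrame) -> list[str]:
    """Locus names inferred from paired ``<locus>_a1``/``<locus>_a2`` columns."""
    loci = [c[:-3] for c in df.columns if c.endswith("_a1")]
    for locus in loci:
        if f"{locus}_a2" not in df.columns:
            raise ValueError(f"locus {locus}: column {locus}_a2 missing")
    return loci


def _allele_array(df: pd.DataFrame, loci: Sequence[str]) -> np.ndarray:
    """(n_samples, n_loci, 2) sorted int array, MISSING = -1.

    A locus is missing if either allele column is blank/NaN.
    """
    n = len(df)
    arr = np.full((n, len(loci), 2), MISSING, dtype=np.int32)
    for j, locus in enumerate(loci):
        a1 = pd.to_numeric(df[f"{locus}_a1"], errors="coerce").to_numpy(dtype=float)
        a2 = pd.to_numeric(df[f"{locus}_a2"], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(a1) & np.isfinite(a2)
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        arr[ok, j, 0] = lo[ok].astype(np.int32)
        arr[ok, j, 1] = hi[ok].astype(np.int32)
    return arr


def genotypes_from_frame(df: pd.DataFrame) -> list[MultilocusGenotype]:
    """Convert a genotype CSV frame into MultilocusGenotype objects."""
    loci = locus_columns(df)
    arr = _allele_array(df, loci)
    out = []
    sex = df["sex_marker"] if "sex_marker" in df.columns else pd.Series(["UNKNOWN"] * len(df))
    hint = df["individual_id"] if "individual_id" in df.columns else pd.Series([None] * len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        calls = {}
        for j, locus in enumerate(loci):
            pair = arr[i, j]
            calls[locus] = None if pair[0] == MISSING else (int(pair[0]), int(pair[1]))
        s = sex.iloc[i]
        s = "UNKNOWN" if pd.isna(s) or s == "" else str(s)
        h = hint.iloc[i]
        out.append(MultilocusGenotype(str(row["sample_id"]), calls, s,
                                      None if pd.isna(h) else str(h)))
    return out


def screen(nestlings: pd.DataFrame, adults: pd.DataFrame,
           min_typed: int = 9, min_overlap: int = 1,
           max_mismatch: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-against-all identity screen of adult genotypes versus nestlings.

    Both inputs follow the genotype CSV schema (``sample_id``, optional
    ``individual_id`` hint, two allele columns per locus, ``sex_marker``).
    Samples typed at fewer than ``min_typed`` loci are dropped before any
    comparison; surviving pairs are then compared on all mutually typed loci
    (the screening convention of the field's matching software: the locus
    threshold is a per-genotype retention rule, and two retained genotypes
    on a 14-locus panel always share at least ``2 * min_typed - 14`` typed
    loci).  Comparison is restricted to the locus panels' intersection.

    Returns
    -------
    matches : DataFrame of MATCH pairs with columns ``nestling_sample,
        adult_sample, nestling_individual, n_compared, n_mismatch, decision,
        ambiguous`` — pairs involving an adult that matches more than one
        distinct nestling individual carry ``ambiguous=True`` and must be
        excluded from linkage.
    report : per-adult summary with ``adult_sample, n_matches,
        n_individuals, status`` (LINKED / AMBIGUOUS / UNMATCHED).
    """
    empty_matches = pd.DataFrame(columns=["nestling_sample", "adult_sample",
                                          "nestling_individual", "n_compared",
                                          "n_mismatch", "decision", "ambiguous"])
    empty_report = pd.DataFrame(columns=["adult_sample", "n_matches", "n_individuals", "status"])
    if nestlings.empty or adults.empty:
        return empty_matches, empty_report

    loci_n = locus_columns(nestlings)
    loci_a = locus_columns(adults)
    shared = [l for l in loci_n if l in set(loci_a)]
    if not shared:
        raise ValueError("nestling and adult genotype panels share no loci")

    na = _allele_array(nestlings, shared)          # (N, L, 2)
    aa = _allele_array(adults, shared)             # (A, L, 2)
    # the >=min_typed filter applies to loci typed on each sample's own panel
    n_typed_n = (_allele_array(nestlings, loci_n)[:, :, 0] != MISSING).sum(axis=1)
    n_typed_a = (_allele_array(adults, loci_a)[:, :, 0] != MISSING).sum(axis=1)
    keep_n = np.flatnonzero(n_typed_n >= min_typed)
    keep_a = np.flatnonzero(n_typed_a >= min_typed)
    if keep_n.size == 0 or keep_a.size == 0:
        return empty_matches, empty_report

    na = na[keep_n]
    aa = aa[keep_a]
    n_ids = nestlings["sample_id"].astype(str).to_numpy()[keep_n]
    a_ids = adults["sample_id"].astype(str).to_numpy()[keep_a]
    if "individual_id" in nestlings.columns:
        n_ind = nestlings["individual_id"].astype(str).to_numpy()[keep_n]
    else:
        n_ind = n_ids

    typed_n = na[:, :, 0] != MISSING               # (N, L)
    typed_a = aa[:, :, 0] != MISSING               # (A, L)

    rows = []
    per_adult: dict[str, set] = {}
    for i in range(aa.shape[0]):
        both = typed_n & typed_a[i]                # (N, L)
        equal = np.all(na == aa[i][None, :, :], axis=2)
        n_compared = both.sum(axis=1)
        n_mismatch = (both & ~equal).sum(axis=1)
        hit = (n_compared >= min_overlap) & (n_mismatch <= max_mismatch)
        for j in np.flatnonzero(hit):
            rows.append((n_ids[j], a_ids[i], n_ind[j],
                         int(n_compared[j]), int(n_mismatch[j]), "MATCH"))
            per_adult.setdefault(a_ids[i], set()).add(n_ind[j])

    matches = pd.DataFrame(rows, columns=["nestling_sample", "adult_sample",
                                          "nestling_individual", "n_compared",
                                          "n_mismatch", "decision"])
    amb = {a for a, inds in per_adult.items() if len(inds) > 1}
    matches["ambiguous"] = matches["adult_sample"].isin(amb)

    rep_rows = []
    for a in a_ids:
        inds = per_adult.get(a, set())
        nm = int((matches["adult_sample"] == a).sum())
        status = "AMBIGUOUS" if len(inds) > 1 else ("LINKED" if inds else "UNMATCHED")
        rep_rows.append((a, nm, len(inds), status))
    report = pd.DataFrame(rep_rows, columns=["adult_sample", "n_matches",
                                             "n_individuals", "status"])
    return matches, report


# ---------------------------------------------------------------------------
# probability of identity


def pid_locus(locus: LocusDef) -> float:
    """P(two unrelated HWE individuals share a genotype at this locus).

    PID = 2 (sum p_i^2)^2 - sum p_i^4.
    """
    p = np.asarray(list(locus.allele_frequencies.values()), dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 2.0 * s2 ** 2 - s4


def pid_sib_locus(locus: LocusDef) -> float:
    """P(two full siblings share a genotype at this locus).

    PIDsib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4.
    """
    p = np.asarray(list(locus.allele_frequencies.values()), dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def pid_combined(loci: Iterable[LocusDef], mode: str = "identity") -> float:
    """Product of per-locus identity probabilities across independent loci."""
    loci = list(loci)
    if not loci:
        raise ValueError("pid_combined needs at least one locus")
    if mode == "identity":
        per = [pid_locus(l) for l in loci]
    elif mode == "sib":
        per = [pid_sib_locus(l) for l in loci]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.prod(per))


# ---------------------------------------------------------------------------
# cross-laboratory calibration


def calibrate_datasets(ref_new: pd.DataFrame, ref_old: pd.DataFrame,
                       old: pd.DataFrame, max_discordance: float = 0.1
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align allele sizes of an older genotype dataset to a newer laboratory.

    Microsatellite allele sizes called in different laboratories (different
    chemistry, ladders, scoring software) commonly differ by a small
    systematic integer offset per locus.  ``ref_new``/``ref_old`` are the
    same reference individuals typed in both laboratories (matched on an
    ``individual_id`` column); for each shared locus the offset is the mode
    of the (new - old) allele-size differences over the reference pairs, an
    integer because shifts are systematic and sizes are integer base pairs.
    The offset is applied to the full ``old`` dataset.  Loci whose reference
    pairs still disagree after the offset in more than ``max_discordance`` of
    pairs are flagged UNCALIBRATED and masked (set missing) in the output.

    Returns (calibrated_old, report) where report has one row per shared
    locus: ``locus, offset, n_pairs, n_discordant, concordance, status``.
    """
    if "individual_id" not in ref_new.columns or "individual_id" not in ref_old.columns:
        raise ValueError("reference frames need an individual_id column")
    merged = ref_new.merge(ref_old, on="individual_id", suffixes=("_new", "_old"))
    if merged.empty:
        raise ValueError("no reference individuals shared between laboratories")

    loci_new = set(locus_columns(ref_new))
    loci_old = locus_columns(ref_old)
    shared = [l for l in loci_old if l in loci_new]
    if not shared:
        raise ValueError("reference datasets share no loci")

    calibrated = old.copy()
    rows = []
    for locus in shared:
        diffs = []
        pairs = []
        for _, r in merged.iterrows():
            new_pair = _read_pair(r, locus, "_new")
            old_pair = _read_pair(r, locus, "_old")
            if new_pair is None or old_pair is None:
                continue
            pairs.append((new_pair, old_pair))
            diffs.extend([new_pair[0] - old_pair[0], new_pair[1] - old_pair[1]])
        if not pairs:
            rows.append((locus, 0, 0, 0, np.nan, "NO_DATA"))
            continue
        values, counts = np.unique(np.asarray(diffs, dtype=int), return_counts=True)
        top = counts.max()
        offset = int(values[counts == top].min())  # ties -> smallest offset
        n_disc = sum(1 for new_pair, old_pair in pairs
                     if (old_pair[0] + offset, old_pair[1] + offset) != new_pair)
        conc = 1.0 - n_disc / len(pairs)
        status = "OK" if n_disc / len(pairs) <= max_discordance else "UNCALIBRATED"
        rows.append((locus, offset, len(pairs), n_disc, conc, status))
        if locus in set(locus_columns(old)):
            if status == "OK":
                for suffix in ("_a1", "_a2"):
                    col = f"{locus}{suffix}"
                    vals = pd.to_numeric(calibrated[col], errors="coerce")
                    calibrated[col] = vals + offset
            else:
                calibrated[f"{locus}_a1"] = np.nan
                calibrated[f"{locus}_a2"] = np.nan
    report = pd.DataFrame(rows, columns=["locus", "offset", "n_pairs",
                                         "n_discordant", "concordance", "status"])
    return calibrated, report


def _read_pair(row, locus: str, suffix: str):
    a1 = pd.to_numeric(pd.Series([row.get(f"{locus}_a1{suffix}")]), errors="coerce").iloc[0]
    a2 = pd.to_numeric(pd.Series([row.get(f"{locus}_a2{suffix}")]), errors="coerce").iloc[0]
    if pd.isna(a1) or pd.isna(a2):
        return None
    a1, a2 = int(a1), int(a2)
    return (a1, a2) if a1 <= a2 else (a2, a1)
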