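"""Reading and writing SNP-array quartet data and aberration calls.

Input format is a GenomeStudio-final-report-style tab-separated table with
one row per SNP and per-sample column triplets
``<role>.GType`` / ``<role>.B Allele Freq`` / ``<role>.Log R Ratio`` for the
roles ``mother``, ``father``, ``CV`` (chorionic villi) and optionally ``EM``
(extra-embryonic mesoderm).  Internal coordinates are 1-based inclusive
(array-manifest convention); BED output is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np
import pandas as pd

from .genome import CHROMOSOMES, normalize_chrom

if TYPE_CHECKING:  # pragma: no cover
    from .interpret import AberrationCall
    from .simdata import ProbeMap

logger = logging.getLogger("haplarith")

SAMPLE_ROLES = ("mother", "father", "CV", "EM")
GENOTYPES = ("AA", "AB", "BB", "NC")

_FIELD_SUFFIXES = ("GType", "B Allele Freq", "Log R Ratio")


class FormatError(ValueError):
    """Raised when an input table does not conform to the expected layout."""


@dataclass
class SampleArray:
    """Probe-aligned genotype/BAF/logR tracks for one sample."""

    genotype: np.ndarray  # '<U2' strings in GENOTYPES
    baf: np.ndarray  # float in [0, 1] (NaN allowed for missing)
    logr: np.ndarray  # float, unitless log2 ratio
    sample_role: str

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype="<U2")
        self.baf = np.asarray(self.baf, dtype=float)
        self.logr = np.asarray(self.logr, dtype=float)
        if not (len(self.genotype) == len(self.baf) == len(self.logr)):
            raise ValueError("genotype/baf/logr tracks must have equal length")
        if self.sample_role not in SAMPLE_ROLES:
            raise ValueError(f"unknown sample role {self.sample_role!r}")
        finite = self.baf[np.isfinite(self.baf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("BAF values must lie in [0, 1]")
        bad = ~np.isin(self.genotype, GENOTYPES)
        if bad.any():
            raise ValueError(
                f"invalid genotype strings: {sorted(set(self.genotype[bad]))}"
            )

    def __len__(self) -> int:
        return len(self.genotype)


@dataclass
class TrioQuartet:
    """A family quartet on a shared probe scaffold.

    CV is mandatory (it seeds the phasing); EM is optional.
    """

    probe_map: "ProbeMap"
    mother: SampleArray
    father: SampleArray
    cv: SampleArray
    em: Optional[SampleArray] = None

    def __post_init__(self) -> None:
        n = len(self.probe_map)
        for arr in self.samples().values():
            if len(arr) != n:
                raise ValueError(
                    f"sample {arr.sample_role!r} has {len(arr)} probes, "
                    f"scaffold has {n}"
                )

    def samples(self) -> dict[str, SampleArray]:
        out = {"mother": self.mother, "father": self.father, "CV": self.cv}
        if self.em is not None:
            out["EM"] = self.em
        return out


# ---------------------------------------------------------------------------
# GenomeStudio-style final report
# ---------------------------------------------------------------------------

def write_final_report(quartet: TrioQuartet, path) -> None:
    """Write a quartet as a final-report-style TSV."""
    pm = quartet.probe_map
    data: dict[str, object] = {
        "SNP Name": pm.probe_id,
        "Chr": pm.chromosome,
        "Position": pm.position,
    }
    for role, arr in quartet.samples().items():
        data[f"{role}.GType"] = arr.genotype
        data[f"{role}.B Allele Freq"] = np.round(arr.baf, 6)
        data[f"{role}.Log R Ratio"] = np.round(arr.logr, 6)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_final_report(path) -> TrioQuartet:
    """Read a final-report-style TSV into a :class:`TrioQuartet`.

    Rows with unparseable positions are dropped (count logged); a missing
    mandatory column raises :class:`FormatError` naming the column, and a
    duplicated probe id is an error.
    """
    from .simdata import ProbeMap  # deferred to avoid an import cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("SNP Name", "Chr", "Position"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    roles = [r for r in SAMPLE_ROLES if f"{r}.GType" in df.columns]
    for role in ("mother", "father", "CV"):
        if role not in roles:
            raise FormatError(f"missing sample columns for role {role!r}")
    for role in roles:
        for suffix in _FIELD_SUFFIXES:
            col = f"{role}.{suffix}"
            if col not in df.columns:
                raise FormatError(f"missing mandatory column {col!r}")

    pos = pd.to_numeric(df["Position"], errors="coerce")
    bad = pos.isna() | (pos < 1)
    if bad.any():
        logger.warning("dropped %d rows with unparseable position", int(bad.sum()))
        df = df.loc[~bad].copy()
        pos = pos.loc[~bad]
    df["Position"] = pos.astype(np.int64)

    if df["SNP Name"].duplicated().any():
        dup = df.loc[df["SNP Name"].duplicated(), "SNP Name"].iloc[0]
        raise FormatError(f"duplicated probe id {dup!r}")

    df["Chr"] = [normalize_chrom(c) for c in df["Chr"]]
    order = {c: i for i, c in enumerate(CHROMOSOMES)}
    df = df.sort_values(
        by=["Chr", "Position"], key=lambda s: s.map(order) if s.name == "Chr" else s
    ).reset_index(drop=True)

    pm = ProbeMap(
        probe_id=df["SNP Name"].to_numpy(dtype=object),
        chromosome=df["Chr"].to_numpy(dtype=object),
        position=df["Position"].to_numpy(dtype=np.int64),
        pop_baf=np.full(len(df), 0.5),
    )
    arrays: dict[str, SampleArray] = {}
    for role in roles:
        gt = df[f"{role}.GType"].fillna("NC").to_numpy(dtype="<U2")
        baf = pd.to_numeric(df[f"{role}.B Allele Freq"], errors="coerce").to_numpy()
        logr = pd.to_numeric(df[f"{role}.Log R Ratio"], errors="coerce").to_numpy()
        arrays[role] = SampleArray(gt, baf, logr, role)
    return TrioQuartet(
        probe_map=pm,
        mother=arrays["mother"],
        father=arrays["father"],
        cv=arrays["CV"],
        em=arrays.get("EM"),
    )


# ---------------------------------------------------------------------------
# Aberration calls: BED + JSON
# ---------------------------------------------------------------------------

_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\ttissue\tcopy_state\tparental_origin\t"
    "segregational_origin\tmosaic_fraction\tsize_class"
)


def _call_key(call) -> tuple:
    return (call.chromosome, call.start, call.end, call.copy_state, call.tissue)


def write_calls(calls: Iterable["AberrationCall"], path) -> tuple[str, str]:
    """Write calls as a BED-style file plus a JSON summary.

    ``path`` is a base path; ``<path>.bed`` and ``<path>.json`` are written.
    Overlapping identical calls (same chromosome, copy state and tissue)
    are merged with a logged message.  Returns the two file names.
    """
    merged: dict[tuple, object] = {}
    out: list = []
    for call in calls:
        dup = None
        for prev in out:
            if (
                prev.chromosome == call.chromosome
                and prev.copy_state == call.copy_state
                and prev.tissue == call.tissue
                and prev.start <= call.end
                and call.start <= prev.end
            ):
                dup = prev
                break
        if dup is not None:
            logger.warning(
                "merging overlapping %s calls on chr%s (%s)",
                call.copy_state, call.chromosome, call.tissue,
            )
            dup.start = min(dup.start, call.start)
            dup.end = max(dup.end, call.end)
        else:
            out.append(dataclasses.replace(call))

    bed_path, json_path = f"{path}.bed", f"{path}.json"
    with open(bed_path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for c in out:
            name = f"{c.copy_state}|{c.parental_origin}|{c.segregational_origin}"
            fh.write(
                f"{c.chromosome}\t{c.start - 1}\t{c.end}\t{name}\t"
                f"{round(100 * c.mosaic_fraction)}\t{c.tissue}\t{c.copy_state}\t"
                f"{c.parental_origin}\t{c.segregational_origin}\t"
                f"{c.mosaic_fraction:.4f}\t{c.size_class}\n"
            )
    with open(json_path, "w") as fh:
        json.dump(
            {
                "n_calls": len(out),
                "calls": [dataclasses.asdict(c) for c in out],
            },
            fh,
            indent=2,
            default=lambda o: float(o) if isinstance(o, np.floating) else str(o),
        )
    del merged
    return bed_path, json_path


def read_calls(path) -> list:
    """Read back the JSON summary written by :func:`write_calls`."""
    from .interpret import AberrationCall

    with open(f"{path}.json") as fh:
        payload = json.load(fh)
    out = []
    for rec in payload["calls"]:
        fields = {f.name for f in dataclasses.fields(AberrationCall)}
        out.append(AberrationCall(**{k: v for k, v in rec.items() if k in fields}))
    return out
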