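"""Integron-array coordinate normalization and IS inverted-repeat geometry.

Each strain's sedentary chromosomal integron (SCI) is described by one or
more genomic spans plus insertion-sequence (IS) elements and an integrase
side.  For cross-strain comparison, coordinates are rescaled so the SCI
envelope (first part start to last part end) maps onto [0, 1], and arrays
whose integrase sits on the right are reflected (x -> 1 - x, strands
flipped) so the integrase is always drawn on the left.  Gaps between split
SCI parts are flagged as interspace.

Normalization maps the 1-based inclusive feature endpoints linearly
(start -> 0, end -> 1); this is the convention under which a feature at
[1500, 1600] inside an envelope [1000, 2000] lands at [0.5, 0.6].

Also reports, for a pair of IS elements, whether they form an inverted-repeat
pair and the intervening segment that homologous recombination between them
would invert (no sequence-level recombination is modeled).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd

ORIENTATIONS = ("+", "-", "unknown")


@dataclass(frozen=True)
class ISElement:
    """An insertion-sequence annotation, 1-based inclusive coordinates."""

    start: int
    end: int
    orientation: str = "unknown"
    family: str = "IS"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"IS element start {self.start} > end {self.end}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


@dataclass(frozen=True)
class ArrayAnnotation:
    """One strain's SCI spans, integrase side, and IS elements."""

    strain: str
    sci_parts: tuple[tuple[int, int], ...]
    integrase_side: str = "left"  # side of the envelope the integrase sits on
    is_elements: tuple[ISElement, ...] = ()

    def __post_init__(self) -> None:
        if not self.sci_parts:
            raise ValueError("at least one SCI part span is required")
        for start, end in self.sci_parts:
            if start > end:
                raise ValueError(f"SCI part start {start} > end {end}")
        if self.integrase_side not in ("left", "right"):
            raise ValueError("integrase_side must be 'left' or 'right'")
        env_start, env_end = self.envelope
        for el in self.is_elements:
            if el.start < env_start or el.end > env_end:
                raise ValueError(
                    f"IS element [{el.start}, {el.end}] outside SCI envelope "
                    f"[{env_start}, {env_end}] of strain {self.strain!r}"
                )

    @property
    def envelope(self) -> tuple[int, int]:
        parts = sorted(self.sci_parts)
        return parts[0][0], parts[-1][1]


@dataclass(frozen=True)
class NormalizedInterval:
    start: float
    end: float
    orientation: str = "unknown"
    family: str = ""


@dataclass(frozen=True)
class NormalizedMap:
    """SCI parts, IS elements, and interspace gaps rescaled onto [0, 1]."""

    strain: str
    parts: tuple[tuple[float, float], ...]
    is_elements: tuple[NormalizedInterval, ...]
    gaps: tuple[tuple[float, float], ...]
    reflected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strain": self.strain, "feature": "SCI_part", "start": s, "end": e,
             "orientation": ".", "family": ""}
            for s, e in self.parts
        ]
        rows += [
            {"strain": self.strain, "feature": "IS", "start": el.start,
             "end": el.end, "orientation": el.orientation, "family": el.family}
            for el in self.is_elements
        ]
        rows += [
            {"strain": self.strain, "feature": "interspace", "start": s, "end": e,
             "orientation": ".", "family": ""}
            for s, e in self.gaps
        ]
        return pd.DataFrame(rows)


def _flip(orientation: str) -> str:
    return {"+": "-", "-": "+", "unknown": "unknown"}[orientation]


def normalize_map(annotation: ArrayAnnotation) -> NormalizedMap:
    """Rescale an annotation onto [0, 1], integrase on the left.

    If the integrase side is ``right`` the map is reflected (x -> 1 - x) and
    feature orientations are flipped; ``unknown`` orientations stay unknown.
    Applying the reflection twice is the identity to floating tolerance.
    """
    env_start, env_end = annotation.envelope
    span = env_end - env_start
    if span == 0:
        raise ValueError("degenerate SCI envelope (single position)")

    def scale(x: float) -> float:
        return (x - env_start) / span

    parts = sorted(annotation.sci_parts)
    norm_parts = [(scale(s), scale(e)) for s, e in parts]
    norm_is = [
        NormalizedInterval(scale(el.start), scale(el.end), el.orientation, el.family)
        for el in annotation.is_elements
    ]
    gaps = [
        (scale(parts[i][1]), scale(parts[i + 1][0]))
        for i in range(len(parts) - 1)
        if parts[i + 1][0] > parts[i][1]
    ]
    reflected = annotation.integrase_side == "right"
    if reflected:
        norm_parts = [(1 - e, 1 - s) for s, e in norm_parts][::-1]
        norm_is = [
            NormalizedInterval(1 - el.end, 1 - el.start, _flip(el.orientation), el.family)
            for el in norm_is
        ][::-1]
        gaps = [(1 - e, 1 - s) for s, e in gaps][::-1]
    return NormalizedMap(
        strain=annotation.strain,
        parts=tuple(norm_parts),
        is_elements=tuple(norm_is),
        gaps=tuple(gaps),
        reflected=reflected,
    )


def reflect_map(nmap: NormalizedMap) -> NormalizedMap:
    """Reflect a normalized map (x -> 1 - x, orientations flipped)."""
    return NormalizedMap(
        strain=nmap.strain,
        parts=tuple((1 - e, 1 - s) for s, e in nmap.parts[::-1]),
        is_elements=tuple(
            NormalizedInterval(1 - el.end, 1 - el.start, _flip(el.orientation), el.family)
            for el in nmap.is_elements[::-1]
        ),
        gaps=tuple((1 - e, 1 - s) for s, e in nmap.gaps[::-1]),
        reflected=not nmap.reflected,
    )


@dataclass(frozen=True)
class InversionSegment:
    """Inter-IS segment that recombination between two ISs would invert.

    The segment spans from the end of the upstream IS to the start of the
    downstream IS, exclusive of the IS elements themselves (1-based
    inclusive coordinates).  ``status`` is ``inverted_repeat`` (opposite
    orientations: recombination inverts the segment), ``direct_repeat``
    (same orientations) or ``indeterminate`` (an orientation is unknown).
    """

    status: str
    segment_start: int | None = None
    segment_end: int | None = None

    @property
    def length(self) -> int | None:
        if self.segment_start is None:
            return None
        return self.segment_end - self.segment_start + 1


def inversion_segment(is_a: ISElement, is_b: ISElement) -> InversionSegment:
    """Classify an IS pair and report the recombination-invertible segment."""
    first, second = sorted((is_a, is_b), key=lambda el: el.start)
    if first.end >= second.start:
        raise ValueError(
            f"overlapping IS elements [{first.start},{first.end}] and "
            f"[{second.start},{second.end}]"
        )
    if "unknown" in (is_a.orientation, is_b.orientation):
        return InversionSegment(status="indeterminate")
    if is_a.orientation == is_b.orientation:
        return InversionSegment(status="direct_repeat")
    return InversionSegment(
        status="inverted_repeat",
        segment_start=first.end + 1,
        segment_end=second.start - 1,
    )


def read_feature_table(path: str | Path) -> list[ArrayAnnotation]:
    """Read strain annotations from a TSV or GFF3 file.

    TSV columns: strain, feature_type in {SCI_part, IS, integrase}, start,
    end, strand, and optionally family.  GFF3: seqid is the strain, the same
    feature types in column 3, family taken from a ``family=`` attribute.
    The integrase feature determines the side: nearer the envelope start ->
    left, nearer the end -> right.
    """
    path = Path(path)
    rows: list[dict] = []
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (len(first.split("\t")) == 9 and not first.lower().startswith("strain")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                rows.append(
                    {"strain": f[0], "feature_type": f[2], "start": int(f[3]),
                     "end": int(f[4]), "strand": f[6],
                     "family": attrs.get("family", "IS")}
                )
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
        for _, r in df.iterrows():
            rows.append(
                {"strain": str(r["strain"]), "feature_type": r["feature_type"],
                 "start": int(r["start"]), "end": int(r["end"]),
                 "strand": str(r.get("strand", ".")),
                 "family": str(r["family"]) if "family" in df.columns else "IS"}
            )

    annotations: list[ArrayAnnotation] = []
    for strain in dict.fromkeys(r["strain"] for r in rows):
        mine = [r for r in rows if r["strain"] == strain]
        parts = tuple(
            (r["start"], r["end"]) for r in mine if r["feature_type"] == "SCI_part"
        )
        is_els = tuple(
            ISElement(
                r["start"], r["end"],
                r["strand"] if r["strand"] in ("+", "-") else "unknown",
                r["family"],
            )
            for r in mine if r["feature_type"] == "IS"
        )
        integrases = [r for r in mine if r["feature_type"] == "integrase"]
        side = "left"
        if integrases and parts:
            env_start = min(s for s, _ in parts)
            env_end = max(e for _, e in parts)
            mid = (integrases[0]["start"] + integrases[0]["end"]) / 2
            side = "right" if abs(mid - env_end) < abs(mid - env_start) else "left"
        annotations.append(
            ArrayAnnotation(strain, parts, integrase_side=side, is_elements=is_els)
        )
    return annotations
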