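"""Sequence-level utilities for capture probes, targets and the labeling scheme.

Capture probes are short DNA oligonucleotides (21-23 nt) complementary to
mature miRNAs and coupled to colour-coded microspheres.  Specificity-control
variants carry one or two deliberate mismatches relative to their
perfect-match parent.  The labeling chemistry flanks each miRNA-derived cDNA
with a template-switch adaptor, a shortened poly(A) tail and an RT-primer
overhang, which fixes the length of the detectable biotinylated product.

Mismatch positions are reported 1-based along the probe sequence read 5'->3'.
RNA input (U) is silently normalized to DNA (T) before any comparison, since
the spike-in control is a synthetic RNA while probes are DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ProbeRecord",
    "LabelingScheme",
    "revcomp",
    "mismatch_positions",
    "labeled_cdna_length",
    "load_probe_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Printed adaptor/primer sequences of the labeling protocol.
SMART_ADAPTOR = "TACAAAAAAGCAGGCTAATTAACCCTCACTAAAGGG"  # 36 nt, SMART-16attB1-T3
RT_PRIMER_OVERHANG = "GTGAATTGTTAATACGACTCACTATAGGCGC"  # 31 nt, oligo-dT15-T7 overhang


def _normalize(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, map U->T, and reject anything outside {A,C,G,T}."""
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValueError(
                f"invalid base {seq[i]!r} at position {i + 1} in {what}"
            )
    return s


@dataclass(frozen=True)
class ProbeRecord:
    """One capture-probe (or target) oligo.

    ``mismatch_count`` counts deliberate mismatches versus the perfect-match
    parent probe (``parent_id``); it is 0 exactly when the record is its own
    parent.  ``bead_region`` is the microsphere colour code the probe is
    coupled to, or ``None`` when uncoupled.
    """

    probe_id: str
    sequence: str
    length_nt: int
    target_mirna: str = ""
    mismatch_count: int = 0
    parent_id: str = ""
    bead_region: int | None = None

    def __post_init__(self) -> None:
        seq = _normalize(self.sequence, what=f"probe {self.probe_id!r}")
        object.__setattr__(self, "sequence", seq)
        if self.length_nt != len(seq):
            raise ValueError(
                f"probe {self.probe_id!r}: length_nt={self.length_nt} "
                f"but sequence has {len(seq)} nt"
            )
        if not 18 <= len(seq) <= 30:
            raise ValueError(
                f"probe {self.probe_id!r}: sequence length {len(seq)} outside [18, 30]"
            )
        if self.mismatch_count < 0:
            raise ValueError(f"probe {self.probe_id!r}: negative mismatch_count")
        is_parent = self.parent_id in ("", self.probe_id)
        if (self.mismatch_count == 0) != is_parent:
            raise ValueError(
                f"probe {self.probe_id!r}: mismatch_count={self.mismatch_count} "
                f"inconsistent with parent_id={self.parent_id!r}"
            )


@dataclass(frozen=True)
class LabelingScheme:
    """Flanking sequences added to every miRNA during labeling.

    Defaults are the printed SMART-16attB1-T3 adaptor (36 nt), the
    T7-containing overhang of the oligo-dT15-T7 RT primer (31 nt) and the
    degenerate-oligo(dT)-shortened poly(A) tail of 15 nt.
    """

    smart_adaptor: str = SMART_ADAPTOR
    rt_primer_overhang: str = RT_PRIMER_OVERHANG
    polyA_len: int = 15

    def __post_init__(self) -> None:
        object.__setattr__(self, "smart_adaptor", _normalize(self.smart_adaptor, what="smart_adaptor"))
        object.__setattr__(
            self, "rt_primer_overhang", _normalize(self.rt_primer_overhang, what="rt_primer_overhang")
        )
        if self.polyA_len < 0:
            raise ValueError("polyA_len must be >= 0")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (U accepted on input, read as T).

    Raises ``ValueError`` naming the 1-based position of the first character
    outside {A,C,G,T,U}.
    """
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


def _seq_of(probe) -> str:
    return probe.sequence if hasattr(probe, "sequence") else _normalize(probe)


def mismatch_positions(parent, variant) -> list[int]:
    """1-based positions (5'->3', ascending) where two equal-length probes differ.

    Accepts :class:`ProbeRecord` instances or raw sequences.  No alignment is
    attempted: unequal lengths are an error.
    """
    a, b = _seq_of(parent), _seq_of(variant)
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ ({len(a)} vs {len(b)}); no alignment attempted")
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def labeled_cdna_length(mirna_len: int, scheme: LabelingScheme | None = None) -> int:
    """Length in nt of the biotinylated cDNA produced from one miRNA.

    The product is adaptor + miRNA + poly(A) + RT-primer overhang; with the
    default scheme a mature miRNA of 18-24 nt maps into the 100-110 nt window
    seen on the electropherograms.
    """
    if scheme is None:
        scheme = LabelingScheme()
    if not 15 <= mirna_len <= 30:
        raise ValueError(f"mirna_len {mirna_len} outside plausible range [15, 30]")
    return len(scheme.smart_adaptor) + mirna_len + scheme.polyA_len + len(scheme.rt_primer_overhang)


def load_probe_table() -> list[ProbeRecord]:
    """The packaged capture-probe table (probes, mismatch variants, spike)."""
    from . import beadio  # local import: beadio imports ProbeRecord from here

    path = resources.files("beadquant").joinpath("data/probes.tsv")
    with resources.as_file(path) as p:
        return beadio.read_probe_table(p)
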