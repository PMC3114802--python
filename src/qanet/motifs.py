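"""QARE (quinic-acid response element) scanning with mismatches.

QA-1F binding sites are 12-bp sequences or two 6-bp half-sites separated by
a 4-nt unconstrained spacer (total window 16 bp). Patterns are written over
A/C/G/T plus the IUPAC code R (A or G) and an optional ``{4}`` spacer token;
the spacer positions match anything and never count as mismatches. Scanning
slides the window one base at a time with no overhang, reporting every
offset with at most ``max_mismatch`` mismatches at specified positions
(default 2). N in a sequence matches nothing. Forward strand by default,
since the site set is near-palindromic; reverse-complement scanning is
available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qanet._errors import FormatError, ParameterError, StructuralError

#: The 16 QARE patterns scanned against 1,000-nt upstream regions.
QARE_PATTERN_STRINGS = (
    "GGATAATTATCC", "GGRTAATTATCC", "GGGTAA{4}TTATCC", "GGATAA{4}TTATCC",
    "GGGTAA{4}TTAAGC", "GGTTAT{4}TCATCC", "GGATGA{4}TTAACC",
    "GGCTAA{4}TTAACA", "GGGTAA{4}TTTTCC", "GGCAAA{4}TCATCC",
    "GGATAA{4}TAACCC", "GGGGAA{4}TTATAG", "GGATGA{4}TTCTCC",
    "GGCGAA{4}TTACCC", "CGTTAA{4}TTATTC", "GGCTCA{4}TCATCA",
)

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG"}
_COMPLEMENT = str.maketrans("ACGTRN", "TGCAYN")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled pattern: specified positions within a fixed window."""

    source: str
    positions: tuple  # ((window offset, allowed-base frozenset), ...)
    length: int  # full window length including any spacer
    gap_offset: int | None = None
    gap_length: int = 0

    @property
    def n_specified(self) -> int:
        return len(self.positions)

    def realize(self, rng) -> list:
        """One concrete instance: random allowed base at specified
        positions, random background base in the spacer."""
        bases = list("ACGT")
        site = [bases[rng.integers(4)] for _ in range(self.length)]
        for rel, allowed in self.positions:
            opts = sorted(allowed)
            site[rel] = opts[rng.integers(len(opts))]
        return site


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based start of the window, half-open
    pattern: str
    mismatch_count: int


def compile_pattern(text: str) -> MotifPattern:
    """Compile a pattern string with at most one ``{4}`` spacer token."""
    gap_offset = None
    gap_length = 0
    body = text
    if "{" in text:
        if text.count("{") != 1 or "{4}" not in text:
            raise FormatError(f"malformed spacer token in {text!r}")
        head, tail = text.split("{4}")
        gap_offset = len(head)
        gap_length = 4
        body = head + tail
    positions = []
    rel = 0
    for ch in body:
        if ch not in _IUPAC:
            raise FormatError(f"invalid symbol {ch!r} in pattern {text!r}")
        if gap_offset is not None and rel == gap_offset:
            rel += gap_length
        positions.append((rel, frozenset(_IUPAC[ch])))
        rel += 1
    return MotifPattern(text, tuple(positions), rel, gap_offset, gap_length)


QARE_PATTERNS = tuple(compile_pattern(p) for p in QARE_PATTERN_STRINGS)


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for i, ch in enumerate("ACGTN"):
        table[ord(ch)] = i if ch != "N" else 4
    codes = table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        raise FormatError("sequence contains symbols outside A/C/G/T/N")
    return codes


def scan_sequence(seq: str, pattern: MotifPattern, max_mismatch: int = 2,
                  sequence_id: str = "", offset_step: int = 1) -> list:
    """All windows of ``seq`` matching ``pattern`` with <= max_mismatch
    mismatches at specified positions (step ``offset_step``, no overhang)."""
    if max_mismatch < 0 or offset_step < 1:
        raise ParameterError("max_mismatch >= 0 and offset_step >= 1 required")
    n = len(seq)
    w = pattern.length
    if n < w:
        return []
    codes = _encode(seq)
    n_win = (n - w) // offset_step + 1
    starts = np.arange(n_win) * offset_step
    mismatches = np.zeros(n_win, dtype=np.int32)
    for rel, allowed in pattern.positions:
        ok = np.zeros(5, dtype=bool)
        for b in allowed:
            ok["ACGT".index(b)] = True
        mismatches += ~ok[codes[starts + rel]]
    hits = np.nonzero(mismatches <= max_mismatch)[0]
    return [MotifHit(sequence_id, int(starts[i]), pattern.source,
                     int(mismatches[i])) for i in hits]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_upstream(sequences: dict, patterns=QARE_PATTERNS, max_mismatch: int = 2,
                  expected_length: int = 1000,
                  scan_reverse: bool = False) -> pd.DataFrame:
    """Scan each upstream sequence against every pattern.

    ``sequences`` maps gene id -> sequence (ids must be unique, enforced by
    the mapping; a list of Biopython SeqRecords is also accepted and checked
    for duplicates). Returns one row per gene: ``qare_present``, ``n_hits``,
    ``best_mismatch`` (nan when absent), and ``short_flag`` for sequences
    shorter than ``expected_length``.
    """
    if not isinstance(sequences, dict):
        records = list(sequences)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate sequence ids")
        sequences = {r.id: str(r.seq) for r in records}
    rows = []
    for gene, seq in sequences.items():
        hits = []
        for pat in patterns:
            hits.extend(scan_sequence(seq, pat, max_mismatch, sequence_id=gene))
            if scan_reverse:
                hits.extend(
                    MotifHit(gene, len(seq) - h.offset - pat.length,
                             pat.source + " (rc)", h.mismatch_count)
                    for h in scan_sequence(reverse_complement(seq), pat,
                                           max_mismatch, sequence_id=gene))
        rows.append({
            "gene": gene,
            "qare_present": bool(hits),
            "n_hits": len(hits),
            "best_mismatch": min((h.mismatch_count for h in hits), default=np.nan),
            "short_flag": len(seq) < expected_length,
        })
    return pd.DataFrame(rows).set_index("gene")


def qare_column(table: pd.DataFrame) -> pd.Series:
    """'X'/'' presence column in the style of the gene summary table."""
    return table["qare_present"].map(lambda v: "X" if v else "")
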