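"""Word/phoneme segmentations: the hierarchical timing input of the pipeline.

Segmentations come from a forced aligner; this module only reads them, either
from Praat TextGrid files (interval tiers named ``words`` and ``phones``) or
from a flat TSV dialect ``fragment_id  tier  label  onset_s  offset_s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PhonemeInterval", "WordInterval", "Segmentation", "read_textgrid", "read_tsv"]


@dataclass
class PhonemeInterval:
    label: str
    onset: float
    offset: float


@dataclass
class WordInterval:
    label: str
    onset: float
    offset: float
    phonemes: list[PhonemeInterval] = field(default_factory=list)


@dataclass
class Segmentation:
    """Ordered word intervals, each holding its phoneme intervals."""

    words: list[WordInterval]
    fragment_id: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        last = -float("inf")
        for w in self.words:
            if w.offset <= w.onset:
                raise ValueError(f"word {w.label!r}: offset must exceed onset")
            if w.onset < last:
                raise ValueError(f"word {w.label!r}: onsets must be increasing")
            last = w.onset
            p_last = -float("inf")
            for p in w.phonemes:
                if p.offset <= p.onset:
                    raise ValueError(f"phoneme {p.label!r}: offset must exceed onset")
                if p.onset < p_last:
                    raise ValueError(f"phoneme {p.label!r}: onsets must be increasing")
                if p.onset < w.onset - 1e-9 or p.offset > w.offset + 1e-9:
                    raise ValueError(
                        f"phoneme {p.label!r} not inside word {w.label!r}"
                    )
                p_last = p.onset

    @property
    def word_onsets(self) -> list[float]:
        return [w.onset for w in self.words]

    @property
    def phoneme_onsets(self) -> list[float]:
        return [p.onset for w in self.words for p in w.phonemes]

    @property
    def duration(self) -> float:
        return max((w.offset for w in self.words), default=0.0)


def _nest(word_iv: list[tuple[str, float, float]], phone_iv: list[tuple[str, float, float]], fragment_id: str) -> Segmentation:
    """Attach phoneme intervals to the word interval containing them."""
    words = [WordInterval(lbl, on, off) for lbl, on, off in word_iv]
    wi = 0
    for lbl, on, off in phone_iv:
        mid = 0.5 * (on + off)
        while wi < len(words) and words[wi].offset < mid:
            wi += 1
        if wi >= len(words) or not (words[wi].onset - 1e-9 <= on and off <= words[wi].offset + 1e-9):
            raise ValueError(f"phoneme {lbl!r} [{on}, {off}] not contained in any word")
        words[wi].phonemes.append(PhonemeInterval(lbl, on, off))
    return Segmentation(words=words, fragment_id=fragment_id)


def read_textgrid(path, word_tier: str = "words", phone_tier: str = "phones") -> Segmentation:
    """Read a Praat TextGrid (long or short text format) into a Segmentation.

    Empty-label intervals (silences) are dropped.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    tiers = _parse_textgrid_tiers(text)
    if word_tier not in tiers:
        raise ValueError(f"tier {word_tier!r} not found (have {sorted(tiers)})")
    if phone_tier not in tiers:
        raise ValueError(f"tier {phone_tier!r} not found (have {sorted(tiers)})")
    words = [(l, a, b) for l, a, b in tiers[word_tier] if l.strip()]
    phones = [(l, a, b) for l, a, b in tiers[phone_tier] if l.strip()]
    return _nest(words, phones, fragment_id=Path(path).stem)


def _parse_textgrid_tiers(text: str) -> dict[str, list[tuple[str, float, float]]]:
    # Long format: item [k] blocks with name/xmin/xmax/text fields.
    tiers: dict[str, list[tuple[str, float, float]]] = {}
    if "item [" in text or "item[" in text:
        blocks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
        for block in blocks:
            name_m = re.search(r'name\s*=\s*"([^"]*)"', block)
            if not name_m:
                continue
            intervals = []
            for m in re.finditer(
                r"intervals\s*\[\d+\]\s*:\s*"
                r"xmin\s*=\s*([\d.eE+-]+)\s*"
                r"xmax\s*=\s*([\d.eE+-]+)\s*"
                r'text\s*=\s*"([^"]*)"',
                block,
            ):
                intervals.append((m.group(3), float(m.group(1)), float(m.group(2))))
            tiers[name_m.group(1)] = intervals
        return tiers
    # Short format: quoted tier name followed by xmin xmax "label" triplets.
    tokens = re.findall(r'"[^"]*"|[\d.eE+-]+', text)
    i = 0
    current = None
    while i < len(tokens):
        tok = tokens[i]
        if tok == '"IntervalTier"':
            name = tokens[i + 1].strip('"')
            current = tiers.setdefault(name, [])
            i += 5  # name, xmin, xmax, size
            continue
        if current is not None and i + 2 < len(tokens) and not tok.startswith('"'):
            label = tokens[i + 2].strip('"') if tokens[i + 2].startswith('"') else ""
            current.append((label, float(tok), float(tokens[i + 1])))
            i += 3
            continue
        i += 1
    return tiers


def read_tsv(path, fragment_id: str | None = None) -> Segmentation:
    """Read the TSV dialect ``fragment_id  tier  label  onset_s  offset_s``.

    A header line is permitted.  ``tier`` must be ``words`` or ``phones``.
    If the file holds several fragments, ``fragment_id`` selects one.
    """
    words, phones = [], []
    frag = fragment_id
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if line_no == 0 and parts[1].lower() == "tier":
            continue
        if len(parts) != 5:
            raise ValueError(f"line {line_no + 1}: expected 5 tab-separated fields")
        fid, tier, label, onset, offset = parts
        if fragment_id is not None and fid != fragment_id:
            continue
        if frag is None:
            frag = fid
        elif fid != frag:
            raise ValueError(
                "file contains multiple fragments; pass fragment_id to select one"
            )
        row = (label, float(onset), float(offset))
        if tier == "words":
            words.append(row)
        elif tier == "phones":
            phones.append(row)
        else:
            raise ValueError(f"line {line_no + 1}: unknown tier {tier!r}")
    return _nest(words, phones, fragment_id=frag or "")


def write_tsv(seg: Segmentation, path) -> None:
    """Write a Segmentation in the flat TSV dialect (round-trips read_tsv)."""
    lines = ["fragment_id\ttier\tlabel\tonset_s\toffset_s"]
    for w in seg.words:
        lines.append(f"{seg.fragment_id}\twords\t{w.label}\t{w.onset:.6f}\t{w.offset:.6f}")
    for w in seg.words:
        for p in w.phonemes:
            lines.append(f"{seg.fragment_id}\tphones\t{p.label}\t{p.onset:.6f}\t{p.offset:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
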