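"""Phosphosite sequence windows and iterative motif extraction.

Every phosphosite is represented by a fixed-width window of the protein
sequence centred on the phosphorylated residue ('-' pads past the protein
termini).  Enriched motifs are found by the classic iterative greedy scheme:
at each step the (offset, residue) pair with the smallest binomial tail
probability against the background frequency is fixed, the foreground and
background are restricted to matching windows, and the process repeats until
no pair is simultaneously frequent enough (``min_occurrence``) and
significant enough (``p_threshold``); matched windows are then removed and
extraction restarts for the next motif.

Defaults: window width 13; ``min_occurrence`` 5 and ``p_threshold`` 1e-5 —
both scaled for foregrounds of under a hundred sites (with 76 sites, a motif
carried by half a dozen threonine windows has a binomial tail of a few 1e-6,
so the classic thresholds of 20 occurrences / 1e-6 calibrated for
thousands-of-sites foregrounds would discard real consensus sequences).
Serine- and threonine-centred analyses are always run separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .io import AMINO_ACIDS, ProteinSequenceRecord, ProteinSite

PAD = "-"


@dataclass(frozen=True)
class SiteWindow:
    """A centred, '-'-padded sequence window around one phosphosite."""

    window: str
    origin: ProteinSite | None = None

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError("window width must be odd")

    @property
    def center_residue(self) -> str:
        return self.window[len(self.window) // 2]

    def at(self, offset: int) -> str:
        """Residue at a signed offset from the centre."""
        return self.window[len(self.window) // 2 + offset]


@dataclass
class MotifResult:
    """One extracted motif: selected (offset, residue) mask plus statistics.

    ``score`` is the sum over mask elements of -log10 of the binomial tail
    probability at the step each element was selected; ``fold_increase`` is
    the foreground match fraction over the background match fraction, both
    measured against the foreground/background remaining when extraction of
    this motif started.
    """

    center_class: str
    mask: list[tuple[int, str]]
    score: float
    fold_increase: float
    fg_matches: int
    fg_total: int
    bg_matches: int
    bg_total: int
    step_stats: list[tuple[int, str, int, int, float, float]] = field(default_factory=list)
    # step_stats rows: (offset, residue, k, n, bg_freq, p_value)

    def pattern(self, width: int = 13) -> str:
        """Render as a dotted string, e.g. ``......SP.....`` for S with +1 P."""
        half = width // 2
        chars = ["."] * width
        chars[half] = self.center_class
        for off, res in self.mask:
            chars[half + off] = res
        return "".join(chars)

    def matches(self, window: SiteWindow) -> bool:
        return all(window.at(off) == res for off, res in self.mask)


@dataclass(frozen=True)
class KinaseAnnotation:
    """Kinase-consensus classes matched by one site window."""

    window: SiteWindow
    classes: frozenset[str]


def build_windows(
    sites: Iterable[ProteinSite],
    proteins: Mapping[str, ProteinSequenceRecord],
    width: int = 13,
) -> list[SiteWindow]:
    """Centred windows of ``width`` characters for mapped phosphosites."""
    if width % 2 != 1:
        raise ValueError("width must be odd")
    half = width // 2
    windows = []
    for site in sites:
        seq = proteins[site.protein_acc].sequence
        if not 1 <= site.position <= len(seq):
            raise ValueError(
                f"site position {site.position} outside protein {site.protein_acc}"
            )
        i = site.position - 1
        left = seq[max(0, i - half) : i]
        right = seq[i + 1 : i + 1 + half]
        window = PAD * (half - len(left)) + left + seq[i] + right + PAD * (half - len(right))
        windows.append(SiteWindow(window=window, origin=site))
    return windows


def windows_from_proteome(
    proteins: Mapping[str, ProteinSequenceRecord],
    centers: str = "ST",
    width: int = 13,
) -> list[SiteWindow]:
    """Background windows: one per occurrence of a centre residue type."""
    sites = [
        ProteinSite(protein_acc=acc, position=i + 1, residue=ch)
        for acc, rec in proteins.items()
        for i, ch in enumerate(rec.sequence)
        if ch in centers
    ]
    return build_windows(sites, proteins, width=width)


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))


def _pair_counts(windows: Sequence[SiteWindow], offset: int) -> tuple[dict[str, int], int]:
    """Residue counts at an offset and the non-padding denominator."""
    counts: dict[str, int] = {}
    total = 0
    for w in windows:
        ch = w.at(offset)
        if ch == PAD:
            continue
        counts[ch] = counts.get(ch, 0) + 1
        total += 1
    return counts, total


def motifx_extract(
    fg_windows: Sequence[SiteWindow],
    bg_windows: Sequence[SiteWindow],
    center: str,
    p_threshold: float = 1e-5,
    min_occurrence: int = 5,
) -> list[MotifResult]:
    """Greedy iterative motif extraction for one centre residue class.

    Foreground and background are first restricted to windows centred on
    ``center``.  Ties in the binomial tail are broken by larger match count,
    then smaller signed offset, then alphabetical residue.  Padding
    characters are excluded from both numerators and denominators.
    """
    if center not in "STY":
        raise ValueError("center must be S, T or Y")
    fg = [w for w in fg_windows if w.center_residue == center]
    bg = [w for w in bg_windows if w.center_residue == center]
    if not fg:
        return []
    width = len(fg[0].window)
    half = width // 2
    offsets = [o for o in range(-half, half + 1) if o != 0]

    results: list[MotifResult] = []
    while fg:
        cur_fg = list(fg)
        cur_bg = list(bg)
        round_fg_total = len(cur_fg)
        round_bg_total = len(cur_bg)
        mask: list[tuple[int, str]] = []
        score = 0.0
        steps: list[tuple[int, str, int, int, float, float]] = []
        while True:
            best = None  # (p, -k, offset, residue, bg_freq, n)
            for off in offsets:
                if any(o == off for o, _ in mask):
                    continue
                fg_counts, fg_n = _pair_counts(cur_fg, off)
                bg_counts, bg_n = _pair_counts(cur_bg, off)
                if fg_n == 0 or bg_n == 0:
                    continue
                for res, k in fg_counts.items():
                    if k < min_occurrence:
                        continue
                    freq = bg_counts.get(res, 0) / bg_n
                    if freq == 0.0:
                        continue  # unmodellable background; skip
                    p = binomial_tail(k, fg_n, freq)
                    cand = (p, -k, off, res, freq, fg_n)
                    if best is None or cand[:4] < best[:4]:
                        best = cand
            if best is None or best[0] >= p_threshold:
                break
            p, neg_k, off, res, freq, n = best
            mask.append((off, res))
            score += -_log10(p)
            steps.append((off, res, -neg_k, n, freq, p))
            cur_fg = [w for w in cur_fg if w.at(off) == res]
            cur_bg = [w for w in cur_bg if w.at(off) == res]
        if not mask:
            break
        motif = MotifResult(
            center_class=center,
            mask=sorted(mask),
            score=score,
            fold_increase=(len(cur_fg) / round_fg_total)
            / (len(cur_bg) / round_bg_total)
            if cur_bg
            else float("inf"),
            fg_matches=len(cur_fg),
            fg_total=round_fg_total,
            bg_matches=len(cur_bg),
            bg_total=round_bg_total,
            step_stats=steps,
        )
        results.append(motif)
        matched = {id(w) for w in cur_fg}
        fg = [w for w in fg if id(w) not in matched]
        bg = [w for w in bg if not motif.matches(w)]
    return results


def _log10(p: float) -> float:
    import math

    return math.log10(p) if p > 0 else math.log10(5e-324)


def residue_composition(sites: Iterable[ProteinSite]) -> dict[str, float]:
    """Fractions of phospho-S, -T and -Y among the sites (sum to 1)."""
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    n = len(sites)
    return {res: sum(1 for s in sites if s.residue == res) / n for res in "STY"}


def stp_fraction(windows: Iterable[SiteWindow]) -> float:
    """Fraction of windows with proline immediately C-terminal (+1) of the site."""
    windows = list(windows)
    if not windows:
        raise ValueError("no windows")
    return sum(1 for w in windows if w.at(+1) == "P") / len(windows)


# Kinase consensus patterns evaluated on the window context:
#   prodirected_cdk  minimal Pro-directed (Cdk-type) site S/T-P
#   gsk3             S-x-x-x-S/T priming pattern (+4 Ser/Thr)
#   polo_cdc5        D/E/N-x-S/T (acidic/amide at -2), budding-yeast polo kinase
#   ck2              S/T-x-x-D/E (+3 acidic), casein kinase II
#   ck1              D/E-x(1-2)-S/T (acidic at -1 or -2), casein kinase I
#                    (the phospho-primed CK1 variant needs phospho-context and
#                    is not evaluable from a single window)
def kinase_annotate(window: SiteWindow) -> KinaseAnnotation:
    if window.center_residue not in "ST":
        raise ValueError("kinase consensus annotation requires an S or T centre")
    classes = set()
    if window.at(+1) == "P":
        classes.add("prodirected_cdk")
    if window.at(+4) in "ST":
        classes.add("gsk3")
    if window.at(-2) in "DEN":
        classes.add("polo_cdc5")
    if window.at(+3) in "DE":
        classes.add("ck2")
    if window.at(-1) in "DE" or window.at(-2) in "DE":
        classes.add("ck1")
    return KinaseAnnotation(window=window, classes=frozenset(classes))


def logo_counts(windows: Sequence[SiteWindow]) -> pd.DataFrame:
    """Residue-count matrix (rows = signed offsets, columns = amino acids)."""
    if not windows:
        raise ValueError("no windows")
    half = len(windows[0].window) // 2
    rows = {}
    for off in range(-half, half + 1):
        counts, _ = _pair_counts(windows, off)
        rows[off] = {aa: counts.get(aa, 0) for aa in AMINO_ACIDS}
    return pd.DataFrame.from_dict(rows, orient="index")


def motif_table(results: Sequence[MotifResult], width: int = 13) -> pd.DataFrame:
    """Motif results as a flat table (pattern, score, fold, counts, coverage)."""
    return pd.DataFrame(
        {
            "pattern": [m.pattern(width) for m in results],
            "center": [m.center_class for m in results],
            "score": [m.score for m in results],
            "fold_increase": [m.fold_increase for m in results],
            "fg_matches": [m.fg_matches for m in results],
            "fg_total": [m.fg_total for m in results],
            "bg_matches": [m.bg_matches for m in results],
            "bg_total": [m.bg_total for m in results],
        }
    )
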