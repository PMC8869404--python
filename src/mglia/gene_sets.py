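"""Published cross-study gene lists and cell-type marker panels.

``GeneSet`` is the direction-annotated gene list used by the overlap
statistics: a named collection of gene symbols, each optionally labelled
``"up"`` or ``"down"``.  Symbols are matched case-insensitively after
whitespace stripping; mouse-style capitalization is preserved on output.

The module also ships the two published overlap comparisons between the
Machado–Joseph disease (MJD) microglial signature and microglial signatures
of the SOD1-G93A amyotrophic-lateral-sclerosis model and the App-NL-G-F
Alzheimer model, restricted to the printed overlapping genes with their
per-study directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _canon(symbol: str) -> str:
    return symbol.strip().casefold()


@dataclass
class GeneSet:
    """A named gene list with optional per-gene direction annotation."""

    name: str
    members: tuple[str, ...]
    directions: dict[str, str] | None = None
    _canon_map: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        cleaned = tuple(m.strip() for m in self.members)
        canon = [_canon(m) for m in cleaned]
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise ValueError(f"duplicate gene symbols in set {self.name!r}: {dupes}")
        self.members = cleaned
        self._canon_map = dict(zip(canon, cleaned))
        if self.directions is not None:
            dirs = {_canon(g): d for g, d in self.directions.items()}
            bad = {d for d in dirs.values()} - {"up", "down"}
            if bad:
                raise ValueError(f"invalid direction labels {sorted(bad)}; use 'up'/'down'")
            missing = [m for m in canon if m not in dirs]
            if missing:
                raise ValueError(
                    f"set {self.name!r} lacks directions for {len(missing)} members"
                )
            self.directions = {g: dirs[_canon(g)] for g in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def canonical_symbols(self) -> set[str]:
        return set(self._canon_map)

    def direction_of(self, symbol: str) -> str:
        if self.directions is None:
            raise KeyError(f"gene set {self.name!r} carries no direction annotation")
        key = _canon(symbol)
        if key not in self._canon_map:
            raise KeyError(f"gene {symbol!r} not in set {self.name!r}")
        return self.directions[self._canon_map[key]]


def _paired(name_a: str, name_b: str, pairs: dict[str, tuple[str, str]]) -> tuple[GeneSet, GeneSet]:
    genes = tuple(pairs)
    a = GeneSet(name_a, genes, {g: d for g, (d, _) in pairs.items()})
    b = GeneSet(name_b, genes, {g: d for g, (_, d) in pairs.items()})
    return a, b


# MJD vs SOD1-G93A (ALS model) microglia: the 27 printed overlapping genes
# with (direction in MJD, direction in ALS).
_ALS_PAIRS: dict[str, tuple[str, str]] = {
    # concordant, up in both (14)
    "Lamc1": ("up", "up"),
    "Hipk3": ("up", "up"),
    "Lrrc58": ("up", "up"),
    "Bmpr2": ("up", "up"),
    "Nav1": ("up", "up"),
    "St8sia4": ("up", "up"),
    "Cpd": ("up", "up"),
    "Fmnl2": ("up", "up"),
    "Atp6v0a1": ("up", "up"),
    "Klhl24": ("up", "up"),
    "Cnot1": ("up", "up"),
    "Tmem106b": ("up", "up"),
    "Xpr1": ("up", "up"),
    "Rnh1": ("up", "up"),
    # concordant, down in both (3)
    "Bend6": ("down", "down"),
    "Usp11": ("down", "down"),
    "Tbkbp1": ("down", "down"),
    # discordant (10)
    "Ncam1": ("up", "down"),
    "Arhgef15": ("up", "down"),
    "Abcb1a": ("up", "down"),
    "Alpl": ("up", "down"),
    "Foxf2": ("up", "down"),
    "Caskin2": ("up", "down"),
    "Fbxl12": ("up", "down"),
    "Gpld1": ("up", "down"),
    "Csad": ("up", "down"),
    "Plin2": ("down", "up"),
}

# MJD vs App-NL-G-F (AD model) microglia: the 31 printed overlapping genes
# with (direction in MJD, direction in AD).
_AD_PAIRS: dict[str, tuple[str, str]] = {
    # concordant, up in both (9)
    "Gm6548": ("up", "up"),
    "Rnf144b": ("up", "up"),
    "Epsti1": ("up", "up"),
    "St8sia4": ("up", "up"),
    "Cpd": ("up", "up"),
    "Fos": ("up", "up"),
    "Junb": ("up", "up"),
    "Acsl4": ("up", "up"),
    "Klhl24": ("up", "up"),
    # concordant, down in both (3)
    "Bend6": ("down", "down"),
    "Phlpp1": ("down", "down"),
    "Rbfox1": ("down", "down"),
    # discordant (19)
    "Cux2": ("up", "down"),
    "Ncam1": ("up", "down"),
    "Arhgef12": ("up", "down"),
    "Mkl2": ("up", "down"),
    "Arhgef15": ("up", "down"),
    "Abcb1a": ("up", "down"),
    "Tyro3": ("up", "down"),
    "Alpl": ("up", "down"),
    "Foxf2": ("up", "down"),
    "Sox8": ("up", "down"),
    "Ahnak": ("up", "down"),
    "Caskin2": ("up", "down"),
    "Scd2": ("up", "down"),
    "Atp2b4": ("up", "down"),
    "Sh2d5": ("up", "down"),
    "Gpld1": ("up", "down"),
    "Syt3": ("up", "down"),
    "Fbxw4": ("down", "up"),
    "Plin2": ("down", "up"),
}

MJD_VS_ALS: tuple[GeneSet, GeneSet] = _paired("MJD_microglia", "ALS_SOD1G93A_microglia", _ALS_PAIRS)
MJD_VS_AD: tuple[GeneSet, GeneSet] = _paired("MJD_microglia", "AD_AppNLGF_microglia", _AD_PAIRS)

#: Reference cell-type marker panels used to check microglial sample purity.
MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "microglia": ("Tmem119", "P2ry12", "Cx3cr1", "Hexb", "C1qa", "Csf1r", "Trem2"),
    "astrocyte": ("Gfap", "Aldh1l1", "Aqp4", "Slc1a3"),
    "neuron": ("Rbfox3", "Syp", "Tubb3", "Snap25"),
    "oligodendrocyte": ("Mbp", "Mog", "Plp1", "Sox10"),
    "endothelial": ("Cldn5", "Pecam1", "Flt1"),
}
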