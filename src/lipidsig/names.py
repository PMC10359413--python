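"""Fatty-acid chain nomenclature.

Variables in a gas-chromatographic FA profile are labelled in shorthand
``C:D`` notation — ``carbons:double_bonds`` — optionally followed by the
methyl-end double-bond series (``n-3``, ``n-6``, ``n-7``, ``n-9``) and
optionally prefixed with ``DMA`` for dimethyl acetals, the transmethylation
derivatives of plasmalogen alkenyl chains.  Examples: ``20:4n-6``,
``DMA 18:0``, ``14:0``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["FAName", "parse_fa_name", "FANameError"]

#: series suffixes accepted in labels; "none" marks chains without one.
SERIES = ("n-3", "n-6", "n-7", "n-9", "none")

_LABEL_RE = re.compile(
    r"""^\s*
        (?P<dma>DMA\s+)?
        (?P<carbons>\d+)
        :
        (?P<db>\d+)
        (?:\s*(?P<series>n-\d+))?
        \s*$""",
    re.VERBOSE | re.IGNORECASE,
)


class FANameError(ValueError):
    """Raised when a variable label cannot be parsed as a fatty-acid chain."""


@dataclass(frozen=True)
class FAName:
    """Parsed identity of one fatty-acid (or alkenyl/DMA) chain.

    Attributes
    ----------
    carbons : int
        Chain length (number of carbon atoms), >= 2.
    double_bonds : int
        Number of carbon-carbon double bonds, >= 0.
    series : str
        Position of the first double bond from the methyl end
        (``n-3``/``n-6``/``n-7``/``n-9``) or ``"none"`` for chains
        without a stated series (all saturated chains).
    is_dma : bool
        True for dimethyl acetals (plasmalogen-derived alkenyl chains).
    """

    carbons: int
    double_bonds: int
    series: str = "none"
    is_dma: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FANameError(f"chain length {self.carbons} < 2")
        if self.double_bonds < 0:
            raise FANameError("negative double bond count")
        if self.series not in SERIES:
            raise FANameError(f"unknown series {self.series!r}")
        if self.double_bonds == 0 and self.series != "none":
            raise FANameError(
                f"saturated chain cannot carry a series suffix ({self.series})"
            )
        if self.double_bonds > 0 and self.series == "none" and not self.is_dma:
            raise FANameError(
                f"unsaturated chain {self.carbons}:{self.double_bonds} "
                "requires a series (n-3/n-6/n-7/n-9)"
            )

    @property
    def label(self) -> str:
        """Canonical label; parsing it reproduces this FAName."""
        s = f"{self.carbons}:{self.double_bonds}"
        if self.series != "none":
            s += self.series
        if self.is_dma:
            s = "DMA " + s
        return s

    @property
    def unsaturation_class(self) -> str:
        """SFA / MUFA / PUFA by double-bond count."""
        if self.double_bonds == 0:
            return "SFA"
        return "MUFA" if self.double_bonds == 1 else "PUFA"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fa_name(label: str) -> FAName:
    """Parse a shorthand fatty-acid label into its structural fields.

    Parameters
    ----------
    label : str
        e.g. ``"20:4n-6"``, ``"DMA 18:0"``, ``"14:0"``.

    Raises
    ------
    FANameError
        If the label is empty or any token is not part of the grammar.
    """
    if not isinstance(label, str) or not label.strip():
        raise FANameError("empty variable label")
    m = _LABEL_RE.match(label)
    if m is None:
        raise FANameError(f"cannot parse FA label {label!r}")
    series = m.group("series")
    if series is not None and series.lower() not in SERIES:
        raise FANameError(f"unknown series token {series!r} in {label!r}")
    try:
        return FAName(
            carbons=int(m.group("carbons")),
            double_bonds=int(m.group("db")),
            series=series.lower() if series else "none",
            is_dma=m.group("dma") is not None,
        )
    except FANameError as err:
        raise FANameError(f"invalid FA label {label!r}: {err}") from None


def is_fa_label(label: str) -> bool:
    """True if ``label`` parses as a fatty-acid chain name."""
    try:
        parse_fa_name(label)
        return True
    except FANameError:
        return False
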