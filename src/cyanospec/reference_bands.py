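"""Published reduced band sets for the imager's design study.

Band centers (nm) of the P1 (nine-peak) and P2 (three-peak) configurations
identified for each retrieval product and data type in the instrument's
spectral-requirements analysis.  Merging the P2 triplets per data type
yields the minimum viable configuration; merging the P1 sets yields the
optimal configuration.
"""

from __future__ import annotations

from .bands import BandSelection

__all__ = ["P2_BANDS", "P1_BANDS", "p2_selection", "p1_selection",
           "minimum_viable_bands"]

# P2: three primary attribution peaks per (product, data_type)
P2_BANDS = {
    ("chl_a", "RRS"): (590, 674, 749),
    ("chl_a", "TOAR"): (614, 686, 722),
    ("chl_a", "BRR"): (614, 686, 722),
    ("pc", "RRS"): (548, 626, 680),
    ("pc", "TOAR"): (548, 632, 710),
    ("pc", "BRR"): (548, 632, 716),
    ("car", "RRS"): (548, 674, 704),
    ("car", "TOAR"): (572, 650, 722),
    ("car", "BRR"): (560, 680, 722),
}

# P1: nine attribution peaks per (product, data_type)
P1_BANDS = {
    ("chl_a", "RRS"): (536, 590, 599, 614, 623, 674, 695, 749, 761),
    ("chl_a", "TOAR"): (506, 530, 566, 614, 656, 686, 722, 764, 782),
    ("chl_a", "BRR"): (512, 572, 614, 638, 674, 686, 722, 764, 782),
    ("pc", "RRS"): (548, 578, 626, 680, 698, 728, 746, 764, 776),
    ("pc", "TOAR"): (548, 608, 632, 662, 698, 710, 740, 758, 770),
    ("pc", "BRR"): (512, 548, 560, 596, 632, 644, 680, 716, 746),
    ("car", "RRS"): (548, 560, 614, 632, 674, 704, 722, 740, 758),
    ("car", "TOAR"): (548, 572, 614, 632, 650, 674, 722, 752, 788),
    ("car", "BRR"): (560, 590, 638, 656, 680, 698, 722, 770, 782),
}


def p2_selection(product: str, data_type: str) -> BandSelection:
    """The published three-band selection for one product and data type."""
    return BandSelection(name="P2", centers=P2_BANDS[(product, data_type)],
                         source=((product, data_type),))


def p1_selection(product: str, data_type: str) -> BandSelection:
    """The published nine-band selection for one product and data type."""
    return BandSelection(name="P1", centers=P1_BANDS[(product, data_type)],
                         source=((product, data_type),))


def minimum_viable_bands(data_type: str) -> tuple:
    """Minimum viable configuration: union of the P2 triplets of all three
    products for one data type."""
    from .bands import merge_configs
    sels = [p2_selection(p, data_type) for p in ("chl_a", "pc", "car")]
    return merge_configs(sels).centers
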