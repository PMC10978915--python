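"""Editing-readout arithmetic for the T7 endonuclease I (T7E1) assay.

T7E1 cleaves heteroduplexes formed by re-annealing PCR products from an
edited locus. From gel band densitometry, the fraction cleaved is

    fraction_cleaved = digested / (digested + parent)

and because a heteroduplex requires pairing one edited with one unedited
strand, the NHEJ event frequency is estimated as

    NHEJ(%) = 100 x [1 - (1 - fraction_cleaved)^(1/2)].

Band densities are plain numbers here; densitometry itself (ImageJ in
practice) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass


class UndefinedMeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class T7E1Measurement:
    density_digested: float
    density_parent: float
    fraction_cleaved: float
    nhej_percent: float


def nhej_percent(density_digested: float, density_parent: float) -> T7E1Measurement:
    """NHEJ(%) from summed cleavage-product and parent band densities.

    Scale-invariant in the densities; strictly increasing in the fraction
    cleaved, mapping 0 -> 0% and 1 -> 100%. Both densities zero is an
    undefined measurement.
    """
    if density_digested < 0 or density_parent < 0:
        raise ValueError("band densities cannot be negative")
    total = density_digested + density_parent
    if total == 0:
        raise UndefinedMeasurementError("both band densities are zero")
    frac = density_digested / total
    nhej = 100.0 * (1.0 - (1.0 - frac) ** 0.5)
    return T7E1Measurement(
        density_digested=density_digested,
        density_parent=density_parent,
        fraction_cleaved=frac,
        nhej_percent=nhej,
    )


def indel_fraction(n_indel_reads: int, n_total_reads: int) -> float:
    """Fraction of reads carrying an InDel at the target locus."""
    if n_total_reads <= 0:
        raise UndefinedMeasurementError("total read count must be positive")
    if not 0 <= n_indel_reads <= n_total_reads:
        raise ValueError("need 0 <= n_indel_reads <= n_total_reads")
    return n_indel_reads / n_total_reads
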