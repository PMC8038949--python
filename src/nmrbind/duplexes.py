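"""DNA duplexes used in the ARID4B Tudor-domain titration experiments.

Strands are stored verbatim as synthesized: ``forward`` reads 5'->3' and
``backward`` reads 3'->5'.  dsDNA1 (18 bp) and dsDNA2 (12 bp) are the
titration duplexes; dsA-tract, dsAT18 and dsGC18 probe the AT-richness
preference of the RGR motif.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DNADuplex", "DNA_DUPLEXES"]


@dataclass(frozen=True)
class DNADuplex:
    name: str
    forward_5to3: str
    backward_3to5: str

    @property
    def length(self) -> int:
        return len(self.forward_5to3)

    @property
    def gc_fraction(self) -> float:
        s = self.forward_5to3
        return sum(c in "GC" for c in s) / len(s)


DNA_DUPLEXES = {
    d.name: d for d in [
        DNADuplex("dsDNA2", "CTGTCAAAGGTG", "ACAGTTTCCACT"),
        DNADuplex("dsDNA1", "CTCAGGTCAAAGGTCACG", "AGTCCAGTTTCCAGTGCT"),
        DNADuplex("dsA-tract", "CGCTTTAAAAAATTTCGG", "GCGAAATTTTTTAAAGCC"),
        DNADuplex("dsAT18", "CGCAATTATATATTACGG", "GCGTTAATATATAATGCC"),
        DNADuplex("dsGC18", "CGCACCGATCCGTGACGG", "GCGTGGCTAGGCACTGCC"),
    ]
}
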