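"""Integron-array map normalization and IS inverted-repeat geometry.

Arrays from different strains are rescaled onto [0, 1] and re-oriented so the
integrase sits on the left, making insertion-sequence (IS) positions
comparable across strains.  For an IS pair, the segment that homologous
recombination between them would invert is reported.
"""

from polyslip import ArrayAnnotation, ISElement, inversion_segment, normalize_map

ann = ArrayAnnotation(
    "strain1",
    sci_parts=((1000, 2000),),
    integrase_side="right",
    is_elements=(ISElement(1500, 1600, "+", family="IS3"),),
)
nm = normalize_map(ann)
el = nm.is_elements[0]
print(f"IS3 at [1500,1600] of envelope [1000,2000], integrase on the right:")
print(f"  normalized to [{el.start:.2f}, {el.end:.2f}], orientation {el.orientation}")
# Reflection puts the integrase on the left: [0.5,0.6] maps to [0.4,0.5]
# and the '+' orientation flips to '-'.

split = ArrayAnnotation("strain2", sci_parts=((0, 400), (600, 1000)))
print("interspace gaps of a split array:", normalize_map(split).gaps)

pair = inversion_segment(ISElement(100, 200, "+"), ISElement(900, 1000, "-"))
print(f"\nIS pair in opposite orientations: {pair.status}")
print(f"recombination would invert [{pair.segment_start}, {pair.segment_end}] "
      f"({pair.length} bp between the two IS copies)")
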