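"""Parse community notation and compute structural descriptors.

A community of N strains interacting via M antibiotics is written as a
bracketed list of N phenotype strings, one letter per antibiotic:
P = producer, S = sensitive, D = degrader, R = intrinsically resistant.
"""

from psdcoex import cyclicity, is_extension, parse_community, psd_coverage

for notation in ["[P,S,D]", "[PD,SP,DS]", "[PD,SP,RS]", "[PDS,SPD,DSP]"]:
    c = parse_community(notation)
    print(
        f"{notation:15s} N={c.n_strains} M={c.n_antibiotics} "
        f"PSD-coverage={psd_coverage(c)} cyclicity={cyclicity(c)} "
        f"canonical={c.canonical().notation}"
    )

child = parse_community("[PDS,SPD,DSP]")
parent = parse_community("[PD,SP,DS]")
print(
    f"\n{child.notation} extends {parent.notation}: "
    f"{is_extension(child, parent)}"
)
print(
    "PSD coverage counts antibiotics with a full producer-sensitive-degrader"
    " motif;\ncyclicity is the largest block of columns related by one-step"
    " cyclic rotation;\nan extension adds antibiotics to a smaller community"
    " without changing its graph."
)
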