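"""Exchange formats: .an transition lists and HyTech-style hybrid text.

The .an dialect carries the discrete automata network; the HyTech
dialect carries the full hybrid network (locations, invariants, rates,
guards) and round-trips through the bundled parser.
"""
from hybridph import build_an, build_network, export_an, load_fixture
from hybridph.hytech import export_hytech, parse_hytech

an = build_an(load_fixture("toy-oscillator"))
print("---- .an export " + "-" * 40)
print(export_an(an))

net = build_network(an)
text = export_hytech(net, name="toy-oscillator")
print("---- HyTech export (gene q only) " + "-" * 24)
in_q = False
for line in text.splitlines():
    if line.startswith("automaton geneq"):
        in_q = True
    if in_q:
        print(line)
    if in_q and line.startswith("end"):
        break

assert export_hytech(parse_hytech(text), name="toy-oscillator") == text
print("\nround trip export -> parse -> export is byte-identical.")
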