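"""Muller potential-apparent-competition indices on a small visitation web.

The PAC matrix d combines each bee's reliance on a plant with another
bee's share of that plant's visits: d[i, j] is the potential of j to
influence i through their shared diet.  The diagonal is the conspecific
(intraspecific) component; averaging a focal species' column over the
other species gives its interspecific competition index.
"""

from bombnet import QuantNetwork, interspecific_index, intraspecific_index, muller_pac

# A relies only on plant x; B splits its visits between x and y.
net = QuantNetwork.from_arrays([[2, 0], [2, 2]],
                               ["B. hypnorum", "B. lucorum/terrestris"],
                               ["Vaccinium", "Trifolium"])
pac = muller_pac(net)
print("PAC matrix (rows sum to 1):")
print(pac.d.round(3))
print()
for focal in pac.taxa:
    intra = intraspecific_index(pac, focal)
    inter = interspecific_index(pac, focal)
    print(f"{focal}: intraspecific d_ff = {intra:.3f}, "
          f"interspecific (mean influence on others) = {inter:.3f}")
print()
print("The generalist (lucorum/terrestris) exerts more influence on the")
print("specialist than the reverse, because it controls half of the")
print("specialist's only food plant while keeping a private resource.")
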