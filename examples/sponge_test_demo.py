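"""The shared-sponge significance test, on a worked example.

A lncRNA-mRNA pair sharing k of the miRNAs that target them is scored by
the upper-tail hypergeometric probability of sharing at least k by chance;
the same statistic drives gene-set over-representation.
"""

from spongenet import network as nw

# 10 eligible miRNAs; the lncRNA is sponged by 4, the mRNA targeted by 5,
# and they share 3. How surprising is that?
p = nw.sponge_test(k=3, K=4, n=5, N=10)
print(f"P(X >= 3 | N=10, K=4, n=5) = {p:.6f}  (66/252 by enumeration)")

# Single shared miRNA: significance then depends entirely on how many
# miRNAs were eligible; below 1/alpha eligible miRNAs it can never reject.
for N in (10, 20, 30, 100):
    print(f"k=K=n=1, N={N:3d}: p = {nw.sponge_test(1, 1, 1, N):.4f}")

# The same machinery scores pathway over-representation of a hit list.
sets = [nw.GeneSet("mapk", frozenset({"MAPK8", "ATF2", "IGF1"})),
        nw.GeneSet("ribosome", frozenset({"RPL3", "RPS6"}))]
universe = {"MAPK8", "ATF2", "IGF1", "PRLR", "SOCS5", "RPL3", "RPS6", "HSP90B1"}
hits = {"MAPK8", "ATF2", "IGF1", "PRLR"}
print(nw.ora_enrichment(hits, sets, universe).to_string(index=False))
# The 'mapk' set holds 3 of the 4 hits out of 8 genes: small p; the
# ribosome set holds none: p = 1.
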