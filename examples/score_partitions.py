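"""Score clustering partitions: adjusted Rand index and biological homogeneity.

The adjusted Rand index compares two partitions of the same observations
(1 = identical up to relabeling, about 0 = unrelated, slightly negative =
worse than chance).  The biological homogeneity index scores one partition
against gene-to-functional-class annotations: the average, over clusters,
of the fraction of annotated gene pairs that share a class.
"""

from gbhc import Partition, adjusted_rand_index, bhi, cluster_count

truth = Partition([1, 1, 1, 2, 2, 2, 3, 3])
good = Partition(["a", "a", "a", "b", "b", "b", "c", "c"])
rough = Partition([1, 1, 2, 2, 2, 2, 3, 3])

print(f"clusters in reference partition: {cluster_count(truth)}")
print(f"ARI(truth, relabeled truth) = {adjusted_rand_index(truth, good):.3f}")
print(f"ARI(truth, rough partition) = {adjusted_rand_index(truth, rough):.3f}")

annotations = {
    0: {"ribosome"}, 1: {"ribosome"}, 2: {"ribosome", "translation"},
    3: {"cell cycle"}, 4: {"cell cycle"}, 5: {"dna repair"},
    6: {"transport"}, 7: set(),  # gene 7 is unannotated
}
print(f"BHI(truth, annotations)     = {bhi(truth, annotations):.3f}")
print("(cluster {0,1,2} fully homogeneous, {3,4,5} one pair in three, "
      "cluster {6,7} has too few annotated genes to count)")
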