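"""Build a reference database from genome records.

Three toy genomes, each with 16S rRNA gene copies and a KO count table, are
clustered at 99% identity; each cluster gets one reference sequence (its
longest member) and one functional profile (the copy-number-normalized,
multiplicity-weighted average over member genomes).
"""

from funred import GenomeRecord, build_reference_database

seq_a = "ACGT" * 100  # two identical 16S copies
seq_b = "TTGG" * 100
genomes = [
    GenomeRecord("genomeA", [seq_a, seq_a], {"K00001": 4, "K00002": 2}),
    GenomeRecord("genomeB", [seq_a, seq_a], {"K00001": 2}),  # same 16S as A
    GenomeRecord("genomeC", [seq_b], {"K00002": 6, "K00003": 3}),
]

db = build_reference_database(genomes, threshold=0.99)

print(f"{len(db.ref_sequences)} references from {len(genomes)} genomes")
print("\nassociation matrix (reference x KO, copy-number normalized):")
print(db.association_matrix.round(3))
print("\npresence fractions (share of member genomes carrying each KO):")
print(db.presence_fraction.round(3))

# genomeA and genomeB share a 16S sequence, so they form one reference whose
# K00001 abundance is the mean of their normalized counts (4/2 and 2/2 copies
# per 16S, each scaled by 2 cluster copies, over 2 genomes = 3.0); K00002 is
# carried by only half the member genomes (presence fraction 0.5).
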