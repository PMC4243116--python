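"""Generate a synthetic protein family and discover its significant patterns.

Three 10-residue motifs are planted in 100 background sequences: two always
appear together (one joint group, present in ~70% of sequences) and one is
drawn independently (also ~70%).  Each planted copy mutates every position
with probability 0.05.  Pattern discovery should recover windows of the
planted motifs with sequence-level support close to 100 x 0.7 x 0.95^len.
"""

from apccooc import JointGroup, Motif, SyntheticSpec, discover_patterns, generate_family

spec = SyntheticSpec(
    motifs=[Motif("KTLHGREVAW", 0.05), Motif("DFYPNCQMIG", 0.05),
            Motif("WSREKTYLVH", 0.05)],
    joint_groups=[JointGroup((0, 1), 0.7)],
    independent_probs={2: 0.7},
    n_sequences=100, length=150, seed=1,
)
seqs, truth = generate_family(spec)
print(f"family: {len(seqs)} sequences of length {len(seqs.records[0])}")

patterns = discover_patterns(seqs)
print(f"{len(patterns)} significant, delta-closed patterns "
      f"(z >= 1.96, support >= 20, delta = 0.9)\n")
print("pattern          support  windows  z-score")
for p in patterns.patterns[:10]:
    print(f"{p.symbols:<16s} {p.support:>7d} {p.occurrence_count:>8d} "
          f"{p.significance:>8.1f}")
print("...\nSupport counts distinct sequences; the z-score is the standard")
print("residual of the window count against an independent-residue background,")
print("so values far above 1.96 mark strongly over-represented motif windows.")
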