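"""Build a frequency PSSM and score query peptides.

The matrix entry PS(i, p) is the fraction of training peptides carrying
residue i at position p; a query is scored by multiplying its position
entries.  In raw mode the score lives in [0, 1] and only a unanimous
consensus reaches 1; in background-odds mode (default) each entry is
divided by the uniform background 1/20, so a score of 1 means "as
likely as random sequence" and larger values indicate motif-like
queries.  A residue never seen at a position zeroes the score.
"""

import slimscan as ss

train = ["KAPPLP", "RTPALP", "KSPPVP", "RAPPLP", "KTPPIP"]
raw = ss.build_pssm(train, L=6, mode="raw")
odds = ss.build_pssm(train, L=6, mode="background_odds")

print("training peptides:", ", ".join(train), "\n")
queries = ["KAPPLP", "RSPPIP", "KAPGLP", "AAAAAA"]
print(f"{'query':8} {'raw':>10} {'background-odds':>16}")
for q in queries:
    print(f"{q:8} {ss.pssm_score(raw, q):>10.5f} {ss.pssm_score(odds, q):>16.1f}")
print("\nA zero raw score means some residue was never observed at that "
      "position in training.")
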