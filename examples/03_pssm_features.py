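"""Turn a PSSM profile into the fixed-length evolutionary feature vector.

A toy profile (positive score on each position's own residue, noisy
negative background) is pooled by residue type: scores are summed per
(residue type, profile column), divided by the sequence length, and
squashed with the logistic, giving 400 values in (0, 1).  Entries on the
diagonal — a residue's own column — should be largest; residue types absent
from the sequence encode as logistic(0) = 0.5.
"""

from spliceid import SyntheticSpec, generate_dataset, generate_pssm, pssm_to_vector
from spliceid.alphabet import AA_INDEX

(rec,), _ = generate_dataset(SyntheticSpec(n_pos=1, n_neg=1, seed=3))
profile = generate_pssm(rec, noise=1.0, seed=5)
vec = pssm_to_vector(profile).reshape(20, 20)

print(f"{rec.id}: length {profile.length}")
for aa in "ARNDC":
    r = AA_INDEX[aa]
    own = vec[r, r]
    off = (vec[r].sum() - own) / 19
    print(f"residue {aa}: own-column {own:.3f}, mean off-column {off:.3f}")
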