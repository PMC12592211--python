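"""Gametologue pairing and NG86 Ks.

Generates male/female SDR protein sets containing three true gametologue
pairs (synonymously diverged to different target Ks) plus one sex-specific
gene per sex, pairs them by reciprocal best hits, and estimates Ka/Ks with
the Nei-Gojobori method. Estimated Ks should track the applied targets;
the sex-specific genes stay unpaired.
"""

import numpy as np

from uvsdr import gametologs
from uvsdr._encode import codes_to_seq
from uvsdr.simulate import _diverge_synonymously, _random_cds_codes

rng = np.random.default_rng(21)
targets = {"pair0": 0.2, "pair1": 0.5, "pair2": 0.9}
cds_m, cds_f = {}, {}
for name, ks in targets.items():
    cds = _random_cds_codes(rng, 600)  # 1.8-kb CDS
    cds_m[f"m_{name}"] = codes_to_seq(cds)
    cds_f[f"f_{name}"] = codes_to_seq(_diverge_synonymously(cds, ks, rng))
cds_m["m_specific"] = codes_to_seq(_random_cds_codes(rng, 600))
cds_f["f_specific"] = codes_to_seq(_random_cds_codes(rng, 600))

prot_m = {g: gametologs.translate_cds(c) for g, c in cds_m.items()}
prot_f = {g: gametologs.translate_cds(c) for g, c in cds_f.items()}
pairs = gametologs.reciprocal_best_hits(prot_m, prot_f)

print("male gene     female gene   target_Ks  est_Ks   est_Ka  saturated")
for m, f, _score in sorted(pairs):
    res = gametologs.kaks_for_cds_pair(cds_m[m], cds_f[f])
    target = targets.get(m.removeprefix("m_"), float("nan"))
    print(f"{m:<13} {f:<13} {target:8.2f}  {res.Ks:6.3f}  {res.Ka:7.4f}"
          f"  {res.saturated}")

classes = gametologs.classify_sdr_genes(sorted(cds_m), sorted(cds_f), pairs)
print("\nSDR gene classes (gametologue = partner found in the opposite "
      "sex's SDR):")
print(classes.to_string(index=False))
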