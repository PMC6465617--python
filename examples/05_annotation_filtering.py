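"""Database-specific annotation-hit filtering and the friendly/unfriendly
risk-burden comparison.
"""

import numpy as np
import pandas as pd

from panprobio.function_filter import filter_hits, risk_burden_compare

hits = pd.DataFrame([
    # KEGG needs query coverage >= 50%
    dict(query_id="g1", subject_id="K00001", database="KEGG",
         identity_pct=85.0, query_len=300, subject_len=310, align_len=160),
    dict(query_id="g2", subject_id="K00002", database="KEGG",
         identity_pct=92.0, query_len=300, subject_len=310, align_len=140),
    # VFDB/CAZy need coverage >= 50% and identity >= 60%
    dict(query_id="g3", subject_id="VFG0001", database="VFDB",
         identity_pct=61.0, query_len=200, subject_len=210, align_len=120),
    dict(query_id="g4", subject_id="GH13", database="CAZy",
         identity_pct=58.0, query_len=200, subject_len=210, align_len=120),
    # ARDB needs both coverages >= 40% and identity above its per-gene cutoff
    dict(query_id="g5", subject_id="ardb_001", database="ARDB",
         identity_pct=82.0, query_len=250, subject_len=240, align_len=110,
         subject_threshold_pct=80.0),
])
accepted = filter_hits(hits)
print(f"accepted {len(accepted)} of {len(hits)} hits:")
for _, r in accepted.iterrows():
    print(f"  {r['query_id']} -> {r['subject_id']} ({r['database']}, "
          f"{r['identity_pct']}% id)")

# risk burden: virulence + resistance gene counts per strain, by source class
rng = np.random.default_rng(0)
counts = pd.Series(
    np.concatenate([rng.poisson(3, 15), rng.poisson(8, 15)]),
    index=[f"strain_{i}" for i in range(30)])
labels = pd.Series(["friendly"] * 15 + ["unfriendly"] * 15, index=counts.index)
res = risk_burden_compare(counts, labels)
print(f"\nrisk burden: friendly mean {res.mean_friendly:.1f} vs unfriendly "
      f"mean {res.mean_unfriendly:.1f}; rank-sum p={res.p:.2e} "
      f"{res.stars or '(ns)'} -> higher in {res.direction} strains")
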