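"""Predict tissue:plasma partition coefficients for the reference compounds.

The mechanistic (Rodgers-Rowland-type) scheme combines tissue water, neutral
lipid/phospholipid partitioning from logPow, and protein association. Kp > 1
means the tissue concentrates the compound relative to plasma.
"""

import qivikit as qk
from qivikit.partitioning import ionization_fractions, predict_partition_set

for rec in (qk.TEBUCONAZOLE, qk.CYROMAZINE):
    ion = ionization_fractions(rec, 7.4)
    pset = predict_partition_set(rec)
    print(f"{rec.name}: logPow {rec.logPow}, fub {rec.fub}, "
          f"neutral fraction at pH 7.4 = {ion['f_neutral']:.3f}")
    for tissue in ("adipose", "muscle", "liver", "kidney", "brain"):
        print(f"  Kp {tissue:8s} = {pset[tissue]:7.3f}")
    vss = sum(pset.kp.values()) / len(pset.kp)
    print(f"  (mean Kp {vss:.2f}; the lipophilic triazole partitions "
          "strongly into fat, the hydrophilic triazine stays near plasma)")
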