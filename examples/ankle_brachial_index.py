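"""Height-corrected ankle-brachial index in the competitive posture.

In the hip-flexed position the ankle sits below the arm, so the blood column
adds 0.78 mmHg per cm of height difference to the measured ankle pressure;
the corrected index and the two normal-value rules (index >= 0.54, between-leg
ankle pressure difference <= 23 mmHg) classify each leg.
"""

import flianirs as fl

left = fl.AbiMeasurement(sap=130.0, sbp=140.0, delta_ab=40.0)
right = fl.AbiMeasurement(sap=100.0, sbp=140.0, delta_ab=40.0)

abi_left = fl.abi_flexed(left)
abi_right = fl.abi_flexed(right)
flags = fl.classify_abi(abi_left, abi_right,
                        sap_left=left.sap, sap_right=right.sap)

print(f"left : SAP {left.sap:.0f} mmHg -> ABI_flexed {abi_left:.4f}  "
      f"abnormal: {flags.left_abnormal}")
print(f"right: SAP {right.sap:.0f} mmHg -> ABI_flexed {abi_right:.4f}  "
      f"abnormal: {flags.right_abnormal}")
print("the right leg is flagged by both the 0.54 rule and the 30 mmHg "
      "between-leg pressure difference")
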