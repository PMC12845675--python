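"""BCI evaluation metrics: accuracy, Cohen's kappa, information transfer.

Shows kappa's chance correction on a worked 10-trial example, then the
speed/accuracy trade-off the ITR formula captures: shorter decision
windows transmit more bits per minute at equal accuracy, which is why a
1-second decoder can beat a 3-second one even after losing some accuracy.
"""

from mstsefnet import accuracy, cohen_kappa, confusion_matrix, itr

y_true = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1]
y_pred = [0, 0, 0, 0, 1, 1, 1, 1, 1, 0]
print(f"accuracy: {accuracy(y_true, y_pred):.0f}%   "
      f"kappa: {cohen_kappa(y_true, y_pred):.2f}  "
      "(70% raw agreement is only kappa 0.4 once chance is removed)")
print("confusion:\n", confusion_matrix(y_true, y_pred, 2))

print("\n4-class ITR (bits/min) across decision windows:")
print(f"{'window':>8} {'P=0.70':>8} {'P=0.80':>8} {'P=0.90':>8}")
for D in (3.0, 2.0, 1.0):
    vals = [itr(P, 4, D) for P in (0.70, 0.80, 0.90)]
    print(f"{D:7.1f}s " + " ".join(f"{v:8.1f}" for v in vals))
print("\nAt fixed accuracy ITR scales as 1/D; at chance (P=1/N) it is 0.")
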