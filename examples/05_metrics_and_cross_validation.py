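"""Classification metrics and the stratified ten-fold protocol.

In this method's literature "specificity" is per-class precision
(TP/(TP+FP)) and "sensitivity" is recall (TP/(TP+FN)), macro-averaged;
the conventional true-negative specificity is reported alongside.
"""

import numpy as np
from sklearn.linear_model import LogisticRegression

from deepfragk import confusion, metrics, ten_fold_cv

# hand-sized example: 2 classes, 10 items
cm = confusion([0] * 5 + [1] * 5, [0] * 5 + [0, 0, 1, 1, 1], n=2)
m = metrics(cm)
print("confusion:", cm.counts.tolist())
print(f"accuracy={m['accuracy']:.2f}  "
      f"macro specificity (precision)={m['macro_specificity']:.3f}  "
      f"macro sensitivity (recall)={m['macro_sensitivity']:.3f}")

# ten-fold CV of a simple classifier on separable synthetic points
rng = np.random.default_rng(0)
X = np.vstack([rng.normal(i, 0.5, size=(30, 2)) for i in range(3)])
y = np.repeat(np.arange(3), 30)
report = ten_fold_cv(X, y, lambda Xt, yt: LogisticRegression().fit(Xt, yt),
                     seed=0)
acc = report.aggregate["accuracy"]
print(f"10-fold accuracy: {acc['mean']:.3f} +/- {acc['sd']:.3f} "
      f"(pooled {report.pooled['accuracy']:.3f})")
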