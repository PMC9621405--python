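"""Collapse 14-observation fine labels onto the five coarse classes.

Maps every one-hot fine vector (one observation positive at a time) and a
combined example.  Each coarse label is the OR over the fine observations
located in that region; `abnormal` is positive for everything except
No Finding.
"""

import numpy as np
import pandas as pd

from cxrlabel.chexpert import OBSERVATIONS, batch_map, map_fine_to_coarse
from cxrlabel.labeler import LABEL_COLUMNS

eye = pd.DataFrame(np.eye(14, dtype=int), columns=list(OBSERVATIONS))
coarse = batch_map(eye)
coarse.insert(0, "observation", OBSERVATIONS)
print(coarse.to_string(index=False))

combined = map_fine_to_coarse({"Fracture": 1, "Cardiomegaly": 1})
print("\nFracture + Cardiomegaly ->", dict(zip(LABEL_COLUMNS, combined.as_tuple())))
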