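"""Published benchmark evaluation grids for three brain-MR tumor datasets.

These are the published extractor x classifier test-accuracy grids for the
BT-small-2c (253 images, 2 classes), BT-large-2c (3000 images, 2 classes) and
BT-large-4c (3064 images, 4 classes) Kaggle brain-MR benchmarks, with 13
ImageNet-pretrained feature extractors scored by the nine-classifier bank.
They are inputs to the selection stage: the row/column aggregation and the
top-3 selection rule can be exercised and audited against them without any
image data or network weights.

Printed grids carry 4-decimal cells; the benchmark's own "Average" column was
computed before rounding, so re-aggregating the printed cells can differ in
the last digit for some rows.  ``PUBLISHED_ROW_MEANS`` / ``PUBLISHED_COLUMN_MEANS``
list only aggregates that are rounding-consistent with their printed cells.
"""

from __future__ import annotations

import io

import pandas as pd

from .features import family_of
from .selection import EvaluationMatrix, matrix_from_tables_layout

__all__ = [
    "BENCHMARK_NAMES",
    "load_benchmark_matrix",
    "PUBLISHED_TOP3",
    "PUBLISHED_ROW_MEANS",
    "PUBLISHED_COLUMN_MEANS",
    "SPLIT_PROTOCOL",
]

BENCHMARK_NAMES = ("bt-small-2c", "bt-large-2c", "bt-large-4c")

#: dataset size and published 80/20 train/test counts
SPLIT_PROTOCOL = {
    "bt-small-2c": {"n": 253, "n_classes": 2, "train": 202, "test": 51},
    "bt-large-2c": {"n": 3000, "n_classes": 2, "train": 2400, "test": 600},
    "bt-large-4c": {"n": 3064, "n_classes": 4, "train": 2611, "test": 653},
}

_COLUMNS = "extractor,fc,gaussian_nb,adaboost,knn,rf,svm_linear,svm_sigmoid,svm_rbf,elm"

_BT_SMALL_2C = f"""{_COLUMNS}
ResNet-50,0.9216,0.8431,0.8431,0.8627,0.8824,0.8235,0.8824,0.9020,0.9020
ResNet-101,0.9216,0.8824,0.8431,0.8235,0.9020,0.8235,0.8824,0.9020,0.8824
DenseNet-121,0.9216,0.7647,0.8235,0.9216,0.8824,0.8431,0.8824,0.8627,0.9020
DenseNet-169,0.9608,0.8039,0.8627,0.9020,0.9412,0.9608,0.9608,0.9804,0.9412
VGG-16,0.8431,0.7451,0.7451,0.7059,0.8431,0.8627,0.8627,0.8039,0.8039
VGG-19,0.8235,0.6863,0.7843,0.6863,0.8235,0.8235,0.8235,0.8235,0.9020
AlexNet,0.9216,0.7255,0.8431,0.7843,0.9020,0.8235,0.8627,0.9020,0.9020
Inception V3,0.9216,0.8824,0.9020,0.8235,0.9412,0.9020,0.9020,0.9020,0.9020
ResNeXt-50,0.9412,0.9020,0.9020,0.9020,0.9216,0.9216,0.9216,0.9216,0.9216
ResNeXt-101,0.9216,0.8039,0.8235,0.8235,0.9020,0.8627,0.9020,0.9216,0.9216
ShuffleNet V2,0.8431,0.7647,0.9216,0.8627,0.9020,0.9412,0.9412,0.9412,0.9412
MobileNet V2,0.8824,0.8431,0.7843,0.8431,0.8824,0.8627,0.8824,0.8824,0.8627
MnasNet,0.9216,0.7843,0.8235,0.8235,0.9216,0.8431,0.8627,0.8627,0.9020
"""

_BT_LARGE_2C = f"""{_COLUMNS}
ResNet-50,0.9767,0.8117,0.9600,0.9767,0.9400,0.9750,0.9750,0.9817,0.9667
ResNet-101,0.9767,0.8250,0.9433,0.9733,0.9567,0.9750,0.9733,0.9800,0.9717
DenseNet-121,0.9750,0.8383,0.9600,0.9817,0.9683,0.9683,0.9683,0.9833,0.9817
DenseNet-169,0.9750,0.8400,0.9650,0.9783,0.9633,0.9667,0.9650,0.9800,0.9800
VGG-16,0.9550,0.7383,0.8833,0.9617,0.9283,0.9517,0.9500,0.9650,0.9550
VGG-19,0.9550,0.7067,0.8850,0.9600,0.9300,0.9550,0.9550,0.9633,0.9450
AlexNet,0.9633,0.7067,0.9200,0.9550,0.9500,0.9400,0.9500,0.9750,0.9633
Inception V3,0.9817,0.8317,0.9567,0.9800,0.9567,0.9750,0.9733,0.9883,0.9800
ResNeXt-50,0.9717,0.8600,0.9550,0.9817,0.9550,0.9700,0.9683,0.9833,0.9750
ResNeXt-101,0.9783,0.8583,0.9633,0.9833,0.9617,0.9717,0.9717,0.9817,0.9817
ShuffleNet V2,0.9433,0.8533,0.9533,0.9700,0.9517,0.9617,0.9617,0.9783,0.9700
MobileNet V2,0.9667,0.8400,0.9367,0.9700,0.9450,0.9617,0.9617,0.9783,0.9633
MnasNet,0.9817,0.8550,0.9467,0.9750,0.9567,0.9700,0.9733,0.9817,0.9833
"""

_BT_LARGE_4C = f"""{_COLUMNS}
ResNet-50,0.8760,0.6937,0.6570,0.8576,0.8530,0.8744,0.8760,0.8989,0.8591
ResNet-101,0.8867,0.7228,0.6799,0.8438,0.8499,0.8897,0.8897,0.9081,0.8683
DenseNet-121,0.8913,0.7106,0.7198,0.8943,0.8744,0.8698,0.8729,0.9158,0.8760
DenseNet-169,0.8959,0.7228,0.7335,0.8821,0.8652,0.8652,0.8729,0.9204,0.8806
VGG-16,0.8760,0.6677,0.7106,0.8331,0.8300,0.8606,0.8606,0.8744,0.8423
VGG-19,0.8683,0.5942,0.6309,0.8346,0.8377,0.8606,0.8606,0.8790,0.8453
AlexNet,0.8637,0.6340,0.6554,0.8714,0.8453,0.8652,0.8683,0.9066,0.8361
Inception V3,0.8652,0.6708,0.6830,0.8300,0.8132,0.8591,0.8591,0.8867,0.8438
ResNeXt-50,0.8744,0.7152,0.6891,0.8775,0.8346,0.8560,0.8576,0.8959,0.8560
ResNeXt-101,0.8851,0.6692,0.7198,0.8714,0.8346,0.8744,0.8744,0.8989,0.8744
ShuffleNet V2,0.8637,0.7152,0.7381,0.8637,0.8576,0.8989,0.8989,0.9112,0.8606
MobileNet V2,0.8928,0.6983,0.7136,0.8897,0.8423,0.8851,0.8851,0.9158,0.8729
MnasNet,0.8851,0.6922,0.7458,0.8928,0.8515,0.8959,0.8959,0.9127,0.8775
"""

_RAW = {
    "bt-small-2c": _BT_SMALL_2C,
    "bt-large-2c": _BT_LARGE_2C,
    "bt-large-4c": _BT_LARGE_4C,
}

#: the published star-marked top-3 selections for each benchmark
PUBLISHED_TOP3 = {
    "bt-small-2c": {"DenseNet-169", "Inception V3", "ResNeXt-50"},
    "bt-large-2c": {"DenseNet-121", "ResNeXt-101", "MnasNet"},
    "bt-large-4c": {"DenseNet-169", "ShuffleNet V2", "MnasNet"},
}

#: published per-extractor "Average" values that re-aggregate exactly from the
#: printed 4-decimal cells
PUBLISHED_ROW_MEANS = {
    ("bt-large-2c", "ResNeXt-101"): 0.9613,
    ("bt-large-4c", "MnasNet"): 0.8499,
}

#: published per-classifier "Average" values, same rounding-consistency filter
PUBLISHED_COLUMN_MEANS = {
    ("bt-large-2c", "svm_rbf"): 0.9785,
    ("bt-large-4c", "svm_rbf"): 0.9019,
}


def load_benchmark_matrix(name: str) -> EvaluationMatrix:
    """Load one published 13 x 9 grid as an :class:`EvaluationMatrix`."""
    if name not in _RAW:
        raise KeyError(f"unknown benchmark {name!r}; expected one of {BENCHMARK_NAMES}")
    df = pd.read_csv(io.StringIO(_RAW[name]), index_col="extractor")
    return matrix_from_tables_layout(df, families={e: family_of(e) for e in df.index})
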