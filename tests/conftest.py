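import numpy as np
import pandas as pd
import pytest
import skbio

from enteroeco.containers import AbundanceTable


@pytest.fixture
def four_point_dm():
    """Two tight pairs far apart: d(A,B)=d(C,D)=1, cross distances 10."""
    D = np.array([[0, 1, 10, 10],
                  [1, 0, 10, 10],
                  [10, 10, 0, 1],
                  [10, 10, 1, 0]], dtype=float)
    return skbio.DistanceMatrix(D, ids=list("ABCD"))


@pytest.fixture
def toy_counts():
    return AbundanceTable(
        pd.DataFrame([[3, 0, 2], [1, 2, 3], [5, 5, 0]],
                     index=["s1", "s2", "s3"], columns=["t1", "t2", "t3"]),
        kind="counts")


@pytest.fixture
def toy_tree_file(tmp_path):
    path = tmp_path / "toy.nwk"
    path.write_text("((A:1,B:1):1,C:2);\n")
    return path


@pytest.fixture
def metadata_file(tmp_path):
    path = tmp_path / "meta.tsv"
    rows = ["sample_id\tseason\taltitude_m\tsex\tbody_temp_C\trmr\tmass_g",
            "s1\twarm\t4761\tF\t39.5\t3.1\t150",
            "s2\tcold\t3118\tM\t38.9\t2.7\t165",
            "s3\twarm\t3900\tF\t39.2\t3.0\t158"]
    path.write_text("\n".join(rows) + "\n")
    return path


def euclidean_dm(X, ids=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    ids = ids or [f"p{i}" for i in range(len(X))]
    return skbio.DistanceMatrix(D, ids=ids)
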