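import numpy as np
import pytest

from ivclass import ExpressionMatrix, RunConfig, SyntheticSpec, generate


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 classes, hand-written values."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 1.1, 5.0, 5.2],
                [2.0, 2.2, 2.1, 1.9],
                [-1.0, 0.5, 0.4, -0.8],
            ]
        ),
        labels={"s1": "x", "s2": "x", "s3": "y", "s4": "y"},
    )


@pytest.fixture
def matrix_files(tmp_path, small_matrix):
    """The small matrix written out as (matrix_path, labels_path)."""
    from ivclass import write_expression_matrix
    from ivclass.data import write_labels

    mp = tmp_path / "matrix.tsv"
    lp = tmp_path / "labels.tsv"
    write_expression_matrix(small_matrix, str(mp))
    write_labels(small_matrix.labels, str(lp), order=small_matrix.sample_ids)
    return str(mp), str(lp)


@pytest.fixture(scope="session")
def tiny_shift():
    """Separable shift dataset small enough for full pipeline tests."""
    spec = SyntheticSpec(
        n_samples_per_class=12,
        n_signature_genes=5,
        n_noise_genes=40,
        effect_size=3.0,
        seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_shift):
    from ivclass import fit

    matrix, _ = tiny_shift
    return fit(matrix, RunConfig())
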