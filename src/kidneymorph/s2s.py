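"""Signed surface-to-surface (S2S) distances.

The per-vertex phenotype: for each template vertex, the Euclidean distance to
the corresponding subject vertex, signed by the projection of the offset onto
the template's outward normal — positive values mean outward expansion of the
subject relative to the template, negative values inward shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriangleMesh, VertexGeometry, vertex_geometry

__all__ = ["S2SMatrix", "s2s", "stack_cohort", "CorrespondedCohort"]


@dataclass
class CorrespondedCohort:
    """Template plus per-subject vertex arrays sharing the template topology."""

    template: TriangleMesh
    subject_vertices: np.ndarray  # (n_s, n_v, 3)
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.subject_vertices = np.asarray(self.subject_vertices, float)
        if self.subject_vertices.ndim != 3 or self.subject_vertices.shape[1:] != (
            self.template.n_vertices,
            3,
        ):
            raise ValueError("subject_vertices must be (n_s, n_v, 3) on template topology")
        if len(self.subject_ids) != len(self.subject_vertices):
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subject_mesh(self, i: int) -> TriangleMesh:
        return TriangleMesh(self.subject_vertices[i], self.template.faces.copy())


@dataclass
class S2SMatrix:
    """n_s x n_v signed distances (mm) with the template they refer to."""

    values: np.ndarray
    subject_ids: list[str]
    template: TriangleMesh | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x vertices)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("S2S values must be finite")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if self.template is not None and self.values.shape[1] != self.template.n_vertices:
            raise ValueError("column count != template vertex count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def column_sds(self, ddof: int = 0) -> np.ndarray:
        return self.values.std(axis=0, ddof=ddof)

    def median_sd(self) -> float:
        """Median over vertices of the per-vertex SD (the mm rescaling unit)."""
        return float(np.median(self.column_sds()))


def s2s(
    template: TriangleMesh,
    subject_vertices: np.ndarray,
    geometry: VertexGeometry | None = None,
) -> np.ndarray:
    """Signed distance from each template vertex to its corresponding subject
    vertex: magnitude = Euclidean distance, sign = sign of the offset's
    projection on the template outward normal."""
    subject_vertices = np.asarray(subject_vertices, float)
    if subject_vertices.shape != template.vertices.shape:
        raise ValueError(
            f"vertex count mismatch: subject {subject_vertices.shape} vs "
            f"template {template.vertices.shape}"
        )
    if geometry is None:
        geometry = vertex_geometry(template)
    offset = subject_vertices - template.vertices
    dist = np.linalg.norm(offset, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", offset, geometry.normals))
    sign[sign == 0] = 1.0  # zero offset -> distance 0 anyway
    return sign * dist


def stack_cohort(
    cohort: CorrespondedCohort, geometry: VertexGeometry | None = None
) -> S2SMatrix:
    """S2S fields for a whole corresponded cohort, rows sorted by subject id."""
    ids = list(cohort.subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if geometry is None:
        geometry = vertex_geometry(cohort.template)
    order = np.argsort(np.asarray(ids, dtype=object))
    rows = [s2s(cohort.template, cohort.subject_vertices[i], geometry) for i in order]
    return S2SMatrix(
        values=np.vstack(rows),
        subject_ids=[ids[i] for i in order],
        template=cohort.template,
    )
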