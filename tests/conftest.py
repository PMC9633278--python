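"""Shared fixtures: tiny constructed feature sets and on-disk fixture files."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from gwalign import Feature, FeatureSet, GeneratorParams, Measure, Peak

FEATUREXML = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <featureMap version="1.9" id="fm_1">
      <!-- upstream feature detection output -->
      <featureList count="2">
        <feature id="f_1">
          <position dim="0">1000.0</position>
          <position dim="1">500.5</position>
          <intensity>4000</intensity>
          <overallquality>0.9</overallquality>
          <charge>2</charge>
          <convexhull nr="0">
            <pt x="995.0" y="500.4"/>
            <pt x="1005.0" y="500.4"/>
            <pt x="1005.0" y="500.6"/>
            <pt x="995.0" y="500.6"/>
          </convexhull>
        </feature>
        <feature id="f_2">
          <position dim="0">1200.0</position>
          <position dim="1">600.25</position>
          <intensity>800</intensity>
          <charge>1</charge>
          <convexhull nr="0">
            <pt x="1195.0" y="600.2"/>
            <pt x="1205.0" y="600.2"/>
            <pt x="1205.0" y="600.3"/>
            <pt x="1195.0" y="600.3"/>
          </convexhull>
        </feature>
      </featureList>
    </featureMap>
    """)


@pytest.fixture
def featurexml_file(tmp_path):
    path = tmp_path / "run1.featureXML"
    path.write_text(FEATUREXML)
    return path


@pytest.fixture
def feature_tsv_file(tmp_path):
    path = tmp_path / "runA.tsv"
    path.write_text(
        "feature_id\trt\tmz\tintensity\n"
        "f1\t100.0\t500.0\t10\n"
        "f1\t102.0\t500.0\t20\n"
        "f1\t104.0\t501.0\t10\n"
        "f2\t300.0\t700.0\t5\n"
    )
    return path


def make_feature(fid: str, rt: float, mz: float, n: int = 3,
                 drt: float = 5.0, dmz: float = 0.5,
                 intensity: float = 10.0) -> Feature:
    """A small synthetic feature: n peaks along a diagonal from (rt, mz)."""
    peaks = [Peak(rt=rt + i * drt, mz=mz + i * dmz, intensity=intensity)
             for i in range(n)]
    return Feature(id=fid, peaks=peaks)


def make_set(source_id: str, specs) -> FeatureSet:
    """specs: iterable of (fid, rt, mz) tuples."""
    return FeatureSet(source_id=source_id,
                      features=[make_feature(fid, rt, mz) for fid, rt, mz in specs])


def random_measure(rng: np.random.Generator, n: int,
                   box: float = 10.0) -> Measure:
    pts = rng.uniform(0, box, size=(n, 2))
    w = rng.uniform(0.1, 1.0, size=n)
    return Measure(points=pts, weights=w / w.sum())


@pytest.fixture
def small_gen_params():
    """Compact generator geometry for fast alignment tests."""
    return GeneratorParams(n_features=15, elution_sigma=6.0, scan_interval=4.0,
                           rt_max=1200.0, seed=7)
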