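"""Round-trip and validation tests for the native spectra dialect, mzML
reading, peak-matrix serialization, and the clinical/IHC table readers."""

import base64
import struct
import textwrap

import numpy as np
import pandas as pd
import pytest

from maldiprofiler import spectra_io as sio
from maldiprofiler.peaks import PeakMatrix


def make_spectrum(case="c1", spot="s1", comp="epithelial", label="FA", n=5):
    return sio.Spectrum(
        mz=np.linspace(800, 900, n),
        intensity=np.linspace(1, 10, n),
        case_id=case,
        spot_id=spot,
        compartment=comp,
        class_label=label,
    )


class TestSpectrumInvariants:
    def test_rejects_negative_intensity(self):
        with pytest.raises(sio.SpectrumValidationError, match="finite and >= 0"):
            sio.Spectrum(mz=[1.0, 2.0], intensity=[1.0, -0.5], case_id="c", spot_id="s")

    def test_rejects_non_increasing_mz(self):
        with pytest.raises(sio.SpectrumValidationError, match="increasing"):
            sio.Spectrum(mz=[1.0, 1.0, 2.0], intensity=[0, 0, 0], case_id="c", spot_id="s")

    def test_rejects_length_mismatch_and_singletons(self):
        with pytest.raises(sio.SpectrumValidationError):
            sio.Spectrum(mz=[1.0, 2.0], intensity=[1.0], case_id="c", spot_id="s")
        with pytest.raises(sio.SpectrumValidationError):
            sio.Spectrum(mz=[1.0], intensity=[1.0], case_id="c", spot_id="s")

    def test_rejects_unknown_compartment_and_label(self):
        with pytest.raises(sio.SpectrumValidationError, match="compartment"):
            make_spectrum(comp="mesenchymal")
        with pytest.raises(sio.SpectrumValidationError, match="class_label"):
            make_spectrum(label="XX")

    def test_dataset_rejects_conflicting_case_labels(self):
        a = make_spectrum(spot="s1", label="FA")
        b = make_spectrum(spot="s2", label="LGP")
        with pytest.raises(sio.SpectrumValidationError, match="conflicting"):
            sio.ProfileDataset(spectra=[a, b])


class TestNativeTabular:
    def test_round_trip_three_spectra(self, tmp_path):
        spectra = [make_spectrum(spot=f"s{i}", n=4 + i) for i in range(3)]
        path = tmp_path / "spectra.csv"
        sio.write_spectra(spectra, path)
        back = sio.read_spectra(path, format="native_tabular")
        assert len(back) == 3
        for a, b in zip(spectra, back):
            np.testing.assert_allclose(a.mz, b.mz)
            np.testing.assert_allclose(a.intensity, b.intensity)
            assert (a.case_id, a.spot_id, a.compartment, a.class_label) == (
                b.case_id, b.spot_id, b.compartment, b.class_label,
            )

    def test_negative_intensity_row_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "case_id": ["c"] * 3, "spot_id": ["s"] * 3,
                "compartment": ["stromal"] * 3, "class_label": ["FA"] * 3,
                "mz": [1.0, 2.0, 3.0], "intensity": [1.0, -2.0, 1.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(sio.SpectraIOError, match="c/s"):
            sio.read_spectra(path)

    def test_missing_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "cols.csv"
        pd.DataFrame({"case_id": [], "mz": [], "intensity": []}).to_csv(path, index=False)
        with pytest.raises(sio.SpectraIOError, match="missing columns"):
            sio.read_spectra(path)


def _mzml_binary(values):
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


def _mzml_spectrum(index, sid, mz, inten):
    return f"""
    <spectrum index="{index}" id="{sid}" defaultArrayLength="{len(mz)}">
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitAccession="MS:1000040" unitName="m/z" unitCvRef="MS"/>
          <binary>{_mzml_binary(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitAccession="MS:1000131" unitName="number of detector counts" unitCvRef="MS"/>
          <binary>{_mzml_binary(inten)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""


def minimal_mzml(spectra_xml):
    return textwrap.dedent(f"""\
    <?xml version="1.0" encoding="utf-8"?>
    <mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
      <run id="r1">
        <spectrumList count="{len(spectra_xml)}" defaultDataProcessingRef="dp1">
          {''.join(spectra_xml)}
        </spectrumList>
      </run>
    </mzML>
    """)


class TestMzml:
    def test_minimal_two_spectrum_fixture(self, tmp_path):
        mz1, i1 = [100.0, 200.0, 300.0], [1.0, 5.0, 2.0]
        mz2, i2 = [150.0, 250.0], [4.0, 0.5]
        xml = minimal_mzml([
            _mzml_spectrum(0, "scan=1", mz1, i1),
            _mzml_spectrum(1, "scan=2", mz2, i2),
        ])
        path = tmp_path / "two.mzML"
        path.write_text(xml)
        spectra = sio.read_spectra(path, format="mzml")
        assert len(spectra) == 2
        np.testing.assert_allclose(spectra[0].mz, mz1)
        np.testing.assert_allclose(spectra[0].intensity, i1)
        np.testing.assert_allclose(spectra[1].mz, mz2)
        np.testing.assert_allclose(spectra[1].intensity, i2)
        assert spectra[0].spot_id == "scan=1"

    def test_negative_intensity_in_mzml_rejected(self, tmp_path):
        xml = minimal_mzml([_mzml_spectrum(0, "scan=1", [100.0, 200.0], [1.0, -3.0])])
        path = tmp_path / "bad.mzML"
        path.write_text(xml)
        with pytest.raises(sio.SpectraIOError, match="scan=1"):
            sio.read_spectra(path, format="mzml")


class TestPeakMatrixIO:
    def _matrix(self, n_spectra=2, n_peaks=3):
        meta = pd.DataFrame(
            {
                "case_id": [f"c{i}" for i in range(n_spectra)],
                "spot_id": [f"s{i}" for i in range(n_spectra)],
                "compartment": ["stromal"] * n_spectra,
                "class_label": ["FA"] * n_spectra,
            }
        )
        mz = np.linspace(900, 1100, n_peaks) + 0.1234
        values = np.arange(n_spectra * n_peaks, dtype=float).reshape(n_spectra, n_peaks)
        return PeakMatrix(meta=meta, mz=mz, values=values)

    def test_two_by_three_layout(self, tmp_path):
        path = tmp_path / "m.csv"
        sio.write_peak_matrix(self._matrix(2, 3), path)
        df = pd.read_csv(path)
        assert df.shape == (2, 7)  # 4 metadata + 3 peak columns

    def test_round_trip_intensities(self, tmp_path):
        m = self._matrix(3, 4)
        path = tmp_path / "m.csv"
        sio.write_peak_matrix(m, path)
        back = sio.read_peak_matrix(path)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-6)
        np.testing.assert_allclose(back.mz, np.round(m.mz, 4))

    def test_empty_peak_list(self, tmp_path):
        m = self._matrix(2, 0)
        path = tmp_path / "empty.csv"
        sio.write_peak_matrix(m, path)
        back = sio.read_peak_matrix(path)
        assert back.values.shape == (2, 0)


class TestClinicalTables:
    def test_extremes_preserved(self, tmp_path):
        path = tmp_path / "clin.csv"
        pd.DataFrame(
            {
                "case_id": ["a", "b"], "group": ["LGP", "LGP"],
                "age": [14, 63], "tumor_size_cm": [1.0, 2.0],
                "followup_months": [10.0, 20.0],
                "recurrence": [False, False], "death_from_disease": [False, False],
                "time_to_event_months": [10.0, 20.0],
            }
        ).to_csv(path, index=False)
        recs = sio.read_clinical_table(path)
        assert sorted(r.age for r in recs) == [14.0, 63.0]

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "case_id,group,age,tumor_size_cm,followup_months,recurrence,"
            "death_from_disease,time_to_event_months\n"
        )
        assert sio.read_clinical_table(path) == []

    def test_non_numeric_age_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "case_id": ["a"], "group": ["FA"], "age": ["forty"],
                "tumor_size_cm": [2.0], "followup_months": [1.0],
                "recurrence": [False], "death_from_disease": [False],
                "time_to_event_months": [1.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(sio.SchemaError):
            sio.read_clinical_table(path)

    def test_missing_mandatory_column_lists_expectation(self, tmp_path):
        path = tmp_path / "cols.csv"
        pd.DataFrame({"case_id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(sio.SchemaError, match="expected"):
            sio.read_clinical_table(path)

    def test_ihc_round_trip(self, tmp_path):
        from maldiprofiler.synthetic_data import generate_ihc_table

        recs = generate_ihc_table(2, 2, 1, seed=0)
        path = tmp_path / "ihc.csv"
        sio.write_ihc_table(recs, path)
        back = sio.read_ihc_table(path)
        assert len(back) == len(recs)
        assert back[0].mean_pct == pytest.approx(recs[0].mean_pct)


class TestImzml:
    def test_round_trip_through_pyimzml_writer(self, tmp_path):
        from pyimzml.ImzMLWriter import ImzMLWriter

        mz = np.array([100.0, 200.0, 300.0])
        path = tmp_path / "toy.imzML"
        with ImzMLWriter(str(path)) as writer:
            writer.addSpectrum(mz, np.array([1.0, 5.0, 2.0]), (1, 1))
            writer.addSpectrum(mz, np.array([2.0, 1.0, 4.0]), (2, 1))
        spectra = sio.read_spectra(path, format="imzml")
        assert len(spectra) == 2
        np.testing.assert_allclose(spectra[0].mz, mz)
        np.testing.assert_allclose(spectra[1].intensity, [2.0, 1.0, 4.0])
        assert spectra[0].spot_id == "x1_y1"
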