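"""Shared fixtures: preset builds and session-scoped renders.

Rendering the oversampled sensor grids costs seconds; images that several
tests inspect (confocal / line-scan pairs, Brillouin renders) are rendered
once per session.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import vipacascade as vc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def confocal():
    """(source, cavities, geometry) of the 785 nm confocal preset."""
    return vc.load_preset("confocal_785").build()


@pytest.fixture(scope="session")
def linescan():
    """(source, cavities, geometry) of the 532 nm line-scanning preset."""
    return vc.load_preset("linescan_532").build()


@pytest.fixture(scope="session")
def confocal_images(confocal):
    """Elastic-line renders without/with the etalon + shared calibration."""
    source, cavities, geometry = confocal
    img_off = vc.render_image(source, [cavities[0]], geometry)
    img_on = vc.render_image(source, cavities, geometry)
    cal = vc.calibrate_image(img_off, cavities[0].fsr_ghz())
    return img_off, img_on, cal


@pytest.fixture(scope="session")
def confocal_curves(confocal_images):
    img_off, img_on, cal = confocal_images
    return (
        vc.extinction_curve(img_off, cal),
        vc.extinction_curve(img_on, cal),
        cal,
    )


@pytest.fixture(scope="session")
def linescan_images(linescan):
    """Line renders: VIPA-only, single 94% etalon, dual 75% cascade."""
    source, cavities, geometry = linescan
    vipa, etalon = cavities
    low = etalon.replace(reflectance_front=0.75, reflectance_back=0.75)
    low = low.replace(thickness_m=vc.matched_etalon_thickness(vipa, low))
    img_off = vc.render_image(source, [vipa], geometry)
    img_on = vc.render_image(source, cavities, geometry)
    img_dual = vc.render_image(source, [vipa, low, low], geometry)
    col = geometry.axis[1]
    cal = vc.calibrate_image(img_off, vipa.fsr_ghz(), column=col)
    return img_off, img_on, img_dual, cal, col


@pytest.fixture(scope="session")
def brillouin_source(confocal):
    """Confocal source carrying the elastic line and a +/- 7 GHz doublet."""
    source, _, _ = confocal
    return source.with_spectrum(
        (
            vc.SpectralLine(0.0, 1.0),
            vc.SpectralLine(-7.0, 0.05),
            vc.SpectralLine(+7.0, 0.05),
        )
    )


@pytest.fixture(scope="session")
def brillouin_fits(confocal, brillouin_source):
    """Noiseless VIPA-only and cascade renders of the doublet, plus fits."""
    _, cavities, geometry = confocal
    fsr = cavities[0].fsr_ghz()
    img_v = vc.render_image(brillouin_source, [cavities[0]], geometry)
    img_c = vc.render_image(brillouin_source, cavities, geometry)
    cal = vc.calibrate_image(img_v, fsr)
    fit_v = vc.fit_brillouin(
        vc.extract_spectrum(img_v, cal, 1), initial_shift_ghz=7.0
    )
    fit_c = vc.fit_brillouin(
        vc.extract_spectrum(img_c, cal, 1), initial_shift_ghz=7.0
    )
    return fit_v, fit_c


@pytest.fixture(scope="session")
def clean_calibration(confocal):
    """Calibration from a noiseless bright synthetic frame."""
    source, cavities, geometry = confocal
    frames, _ = vc.synth_brillouin_stack(
        cavities,
        geometry,
        source,
        vc.TruthRecord(seed=0, poisson=False, read_noise_dn=0.0),
        n_frames=1,
        exposure_s=0.25,
    )
    return vc.calibrate_image(frames[0], cavities[0].fsr_ghz())
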