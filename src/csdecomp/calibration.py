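"""Published aggregate figures used to calibrate the default synthetic cohort.

The study population is nulliparous singleton deliveries in Irish public
maternity hospitals in 2009, split by model of care (public vs private
patient of the consultant).  The record-level data (a HIPE/NPRS linkage) are
not publicly deposited; what is public is a descriptive table of per-group
covariate prevalences and unadjusted caesarean-section counts.  Those
published marginals are transcribed here and drive ``default_spec()``.

Prevalences are stored as published percentages; a handful of columns sum to
100.1 or 99.9 because of printed rounding and are renormalised when turned
into probability vectors.
"""

from __future__ import annotations

# Group sizes and caesarean counts (elective / emergency) per model of care.
STUDY_2009_COUNTS = {
    "public": {"n": 22_059, "elcs": 913, "emcs": 4_325},
    "private": {"n": 7_811, "elcs": 664, "emcs": 1_890},
}

# Published percentage prevalence per covariate level: {level: (public, private)}.
# Binary covariates store the prevalence of the positive level only.

AGE_BANDS = {  # years; (low, high) half-open bands for continuous draws
    "<20": (16.0, 20.0),
    "20-24": (20.0, 25.0),
    "25-29": (25.0, 30.0),
    "30-34": (30.0, 35.0),
    "35-39": (35.0, 40.0),
    ">=40": (40.0, 46.0),
}
AGE_PREVALENCE = {
    "<20": (8.9, 0.5),
    "20-24": (25.0, 1.8),
    "25-29": (34.2, 17.8),
    "30-34": (22.9, 52.5),
    "35-39": (7.9, 23.3),
    ">=40": (1.2, 4.1),
}

SOCIAL_CLASS_PREVALENCE = {
    "professional_managerial": (21.2, 56.5),
    "clerical": (26.0, 27.9),
    "skilled_semi_skilled": (7.3, 3.5),
    "unskilled": (18.2, 7.3),
    "unemployed": (4.6, 0.2),
    "home_duties": (15.1, 1.9),
    "other": (7.5, 2.8),
}

MARRIED_PREVALENCE = (44.9, 83.5)

COUNTRY_OF_BIRTH_PREVALENCE = {
    "ireland": (64.2, 92.1),
    "uk": (2.4, 1.6),
    "eu15": (1.8, 2.1),
    "eu27_accession": (20.9, 1.2),
    "africa": (2.4, 0.2),
    "asia": (5.9, 1.1),
    "other": (2.4, 1.7),
}

PREVIOUS_MISCARRIAGE_PREVALENCE = (13.3, 17.9)

GESTATION_BANDS = {  # weeks
    "<33": (26.0, 33.0),
    "33-37": (33.0, 38.0),
    "38+": (38.0, 42.0),
}
GESTATION_PREVALENCE = {
    "<33": (1.4, 1.2),
    "33-37": (7.8, 7.9),
    "38+": (90.8, 90.9),
}

BIRTHWEIGHT_BANDS = {  # kilograms
    "500-2499": (0.5, 2.5),
    "2500-2999": (2.5, 3.0),
    "3000-3499": (3.0, 3.5),
    "3500-3999": (3.5, 4.0),
    "4000-4499": (4.0, 4.5),
    "4500+": (4.5, 5.2),
}
BIRTHWEIGHT_PREVALENCE = {
    "500-2499": (5.0, 4.1),
    "2500-2999": (13.9, 11.2),
    "3000-3499": (36.5, 34.5),
    "3500-3999": (32.4, 35.3),
    "4000-4499": (10.5, 12.5),
    "4500+": (1.7, 2.4),
}

CLINICAL_RISK_PREVALENCE = {
    "breech": (4.1, 4.9),
    "diabetes_preexisting": (0.3, 0.2),
    "gestational_diabetes": (1.7, 1.0),
    "eclampsia_preeclampsia": (3.2, 3.5),
    "malpresentation": (0.7, 2.0),
    "placenta_praevia_abruption": (0.6, 0.9),
    "hypertensive_disorders": (4.7, 5.0),
    "poor_fetal_growth": (2.5, 2.3),
    "induction": (28.9, 34.4),
}

TEACHING_HOSPITAL_PREVALENCE = (47.5, 60.9)
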