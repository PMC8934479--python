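{
  "description": "Published deployment figures of the Self Audit medication-safety system in Catalan primary care, 2016-2018: April (baseline) and December (final) MRP counts per category, AEMPS-alert detail, prevalence denominators and indicator-linked resolution counts. Rows whose printed percentage column could not be reconciled with the printed counts are omitted.",
  "table2": {
    "2016": {
      "duplicate_therapies": [46242, 41589, -4653, -10],
      "aemps_safety_alerts": [13521, 6849, -6672, -49],
      "contraindications": [37359, 37421, 62, 0],
      "bisphosphonates_5y": [8246, 7434, -812, -10],
      "double_antiplatelet_12m": [4805, 4332, -473, -10],
      "geriatric_inadvisable": [88393, 83638, -4755, -5],
      "anticholinergic_combination": [2913, 2320, -593, -20],
      "avoidable_medication": [30984, 27333, -3651, -12],
      "total": [232463, 210916, -21547, -9]
    },
    "2017": {
      "duplicate_therapies": [65679, 59536, -6143, -9],
      "aemps_safety_alerts": [11212, 9935, -1277, -11],
      "contraindications": [44687, 44000, -687, -2],
      "bisphosphonates_5y": [6386, 4964, -1422, -22],
      "double_antiplatelet_12m": [4394, 4508, 114, 3],
      "geriatric_inadvisable": [82252, 79187, -3065, -4],
      "anticholinergic_combination": [2184, 1819, -365, -17],
      "avoidable_medication": [26986, 23907, -3079, -11],
      "total": [243780, 227856, -15924, -7]
    },
    "2018": {
      "duplicate_therapies": [65377, 64650, -727, -1],
      "aemps_safety_alerts": [7046, 5441, -1605, -23],
      "contraindications": [45175, 46469, 1294, 3],
      "bisphosphonates_5y": [4552, 4123, -429, -9],
      "double_antiplatelet_12m": [4631, 4630, -1, 0],
      "geriatric_inadvisable": [79225, 79384, 159, 0],
      "anticholinergic_combination": [1854, 1736, -118, -6],
      "avoidable_medication": [25491, 24526, -965, -4],
      "total": [233351, 230959, -2392, -1]
    }
  },
  "table3": {
    "2016": {
      "triple_whammy": [9767, 3356, -6411, -66],
      "coxibs": [407, 282, -125, -31],
      "diclofenac": [325, 144, -181, -56],
      "cilostazol": [115, 105, -10, -9],
      "ivabradine": [102, 88, -14, -14],
      "aceclofenac": [82, 60, -22, -27],
      "agomelatine": [74, 62, -12, -16],
      "escitalopram": [55, 51, -4, -7],
      "citalopram": [41, 34, -7, -17],
      "trimetazidine": [40, 27, -13, -33],
      "raloxifene_bazedoxifene": [14, 9, -5, -36],
      "aliskiren": [5, 4, -1, -20]
    },
    "2017": {
      "triple_whammy": [4123, 2242, -1881, -46],
      "coxibs": [349, 240, -109, -31],
      "diclofenac": [189, 109, -80, -42],
      "cilostazol": [107, 82, -25, -23],
      "ivabradine": [87, 73, -14, -16],
      "aceclofenac": [69, 43, -26, -38],
      "agomelatine": [78, 69, -9, -12],
      "escitalopram": [54, 61, 7, 13],
      "citalopram": [48, 47, -1, -2],
      "trimetazidine": [34, 24, -10, -29],
      "raloxifene_bazedoxifene": [10, 7, -3, -30],
      "aliskiren": [2, 3, 1, 50]
    },
    "2018": {
      "triple_whammy": [3260, 1850, -1410, -43],
      "coxibs": [384, 283, -101, -26],
      "diclofenac": [189, 96, -93, -49],
      "cilostazol": [101, 78, -23, -23],
      "aceclofenac": [51, 28, -23, -45]
    }
  },
  "triple_whammy_share": {
    "2016": {"triple_whammy": 9767, "total_alerts": 11035, "share_pct": 89},
    "2017": {"triple_whammy": 4123, "total_alerts": 5153, "share_pct": 80},
    "2018": {"triple_whammy": 3260, "total_alerts": 4460, "share_pct": 73}
  },
  "prevalence": {
    "2016": {"mrp_count": 210916, "active_prescriptions": 9500000, "pct": 2.2},
    "2017": {"mrp_count": 227856, "active_prescriptions": 9600000, "pct": 2.4},
    "2018": {"mrp_count": 230959, "active_prescriptions": 9700000, "pct": 2.4}
  },
  "indicator": {
    "2016": {
      "resolved": {"duplicate_therapy": 5413, "aemps_alert": 6815, "polymedication": 5130},
      "total_resolved": 17358,
      "december_linked_total": 24720,
      "resolution_pct": 41
    },
    "2017": {
      "resolved": {"duplicate_therapy": 4892, "aemps_alert": 2160, "polymedication": 603},
      "total_resolved": 7655,
      "december_linked_total": null,
      "resolution_pct": null
    },
    "2018": {
      "resolved": {"duplicate_therapy": 3485, "aemps_alert": 1735, "polymedication": 2915},
      "total_resolved": 8135,
      "december_linked_total": 31501,
      "resolution_pct": 21
    },
    "all_years_total": 33148,
    "overall_resolved_all_mrps": 41492,
    "linked_share_pct": 80
  },
  "december_2018_composition": {
    "total": 230959,
    "geriatric_inadvisable": {"count": 79384, "share_pct": 34},
    "duplicate_therapies": {"count": 64650, "share_pct": 28},
    "contraindications": {"count": 46469, "share_pct": 20},
    "top3_count": 190503,
    "top3_share_pct": 82.5
  }
}
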