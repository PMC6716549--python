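"""The printed zone-wise abundance-change table, transcribed for regression.

Per zone: ``species -> (count_start, contrib_start, count_end, contrib_end,
cc)`` with contributions kept as the printed strings (their decimal precision
varies) and ``None`` for dash cells.

Two printed cells are internally inconsistent with the table's own counts
and are listed in ``ERRATA`` with the value implied by the counts:

* the climax species' 1986 hyposaline contribution prints 41.43 but
  8525/20378 = 41.83 (its printed %CC, +3.12, only reproduces from 41.83);
* one rare species' hyposaline %CC prints +4.75 where the counts give +4.74.
"""

HYPOSALINE = {
    "Excoecaria agallocha":   (9572, "46.97", 8634, "46.59", -0.41),
    "Heritiera fomes":        (8525, "41.43", 8253, "44.53", 3.12),
    "Avicennia officinalis":  (568, "2.79", 193, "1.04", -45.60),
    "Sonneratia apetala":     (436, "2.14", 116, "0.63", -54.73),
    "Amoora cucullata":       (350, "1.72", 337, "1.82", 2.85),
    "Bruguiera sexangula":    (290, "1.42", 339, "1.83", 12.49),
    "Xylocarpus moluccensis": (198, "0.97", 297, "1.60", 24.51),
    "Cynometra ramiflora":    (180, "0.88", 14, "0.08", -84.24),
    "Cerbera manghas":        (130, "0.64", 21, "0.11", -69.83),
    "Talipariti tiliaceum":   (59, "0.29", 31, "0.17", -26.76),
    "Aegiceras corniculatum": (33, "0.16", 15, "0.08", -33.35),
    "Excoecaria indica":      (8, "0.04", 4, "0.02", -29.05),
    "Tamarix dioica":         (8, "0.04", 3, "0.02", -41.61),
    "Barringtonia racemosa":  (7, "0.03", 0, "0.00", -100.0),
    "Ceriops decandra":       (4, "0.02", 258, "1.39", 97.22),
    "Sonneratia caseolaris":  (3, "0.01", 0, "0.00", -100.0),
    "Intsia bijuga":          (2, "0.01", 3, "0.02", 24.51),
    "Lannea coromandelica":   (2, "0.01", 0, "0.00", -100.0),
    "Xylocarpus granatum":    (1, "0.005", 9, "0.05", 81.64),
    "Pongamia pinnata":       (1, "0.005", 2, "0.01", 37.48),
    "Syzygium fruticosum":    (1, "0.005", 1, "0.006", 4.75),
    "Hypobathrum racemosum":  (0, None, 3, "0.02", 100.0),
}

MESOSALINE = {
    "Excoecaria agallocha":   (7338, "47.95", 9301, "56.34", 8.04),
    "Heritiera fomes":        (7754, "50.67", 5998, "36.33", -16.48),
    "Avicennia officinalis":  (1, "0.01", 0, None, -100.0),
    "Amoora cucullata":       (51, "0.33", 33, "0.20", -25.02),
    "Bruguiera sexangula":    (1, "0.01", 1, "0.01", -3.79),
    "Xylocarpus moluccensis": (38, "0.25", 41, "0.25", 0.01),
    "Cynometra ramiflora":    (71, "0.46", 19, "0.12", -60.25),
    "Ceriops decandra":       (20, "0.13", 1098, "6.65", 96.15),
    "Xylocarpus granatum":    (14, "0.09", 12, "0.07", -11.45),
    "Hypobathrum racemosum":  (0, "0.00", 4, "0.02", 100.0),
    "Salacia chinensis":      (12, "0.08", 0, "0.00", -100.0),
    "Rhizophora mucronata":   (0, "0.00", 1, "0.01", 100.0),
    "Lumnitzera racemosa":    (3, "0.02", 1, "0.01", -52.79),
}

HYPERSALINE = {
    "Excoecaria agallocha":   (9505, "85.32", 11558, "80.45", -2.94),
    "Heritiera fomes":        (1215, "10.91", 1009, "7.02", -21.66),
    "Avicennia officinalis":  (6, "0.05", 4, "0.03", -31.84),
    "Sonneratia apetala":     (5, "0.04", 3, "0.02", -36.49),
    "Amoora cucullata":       (57, "0.51", 41, "0.29", -28.39),
    "Bruguiera sexangula":    (4, "0.04", 5, "0.03", -1.56),
    "Xylocarpus moluccensis": (76, "0.68", 69, "0.48", -17.37),
    "Ceriops decandra":       (257, "2.31", 1669, "11.62", 66.87),
    "Xylocarpus granatum":    (16, "0.14", 9, "0.06", -39.26),
}

PRINTED = {
    "hyposaline": HYPOSALINE,
    "mesosaline": MESOSALINE,
    "hypersaline": HYPERSALINE,
}

TOTALS = {
    ("hyposaline", 1986): 20378,
    ("hyposaline", 2014): 18533,
    ("mesosaline", 1986): 15303,
    ("mesosaline", 2014): 16509,
    ("hypersaline", 1986): 11141,
    ("hypersaline", 2014): 14367,
}

# (zone, species, field) -> value implied by the printed counts, where the
# printed cell itself is a typo (see module docstring).
ERRATA = {
    ("hyposaline", "Heritiera fomes", "contrib_start"): 41.83,
    ("hyposaline", "Syzygium fruticosum", "contrib_end"): 0.005,
    ("hyposaline", "Syzygium fruticosum", "cc"): 4.74,
}
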