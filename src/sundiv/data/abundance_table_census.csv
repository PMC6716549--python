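plot_id,zone,year,species,count
hyposaline,hyposaline,1986,Excoecaria agallocha,9572
hyposaline,hyposaline,1986,Heritiera fomes,8525
hyposaline,hyposaline,1986,Avicennia officinalis,568
hyposaline,hyposaline,1986,Sonneratia apetala,436
hyposaline,hyposaline,1986,Amoora cucullata,350
hyposaline,hyposaline,1986,Bruguiera sexangula,290
hyposaline,hyposaline,1986,Xylocarpus moluccensis,198
hyposaline,hyposaline,1986,Cynometra ramiflora,180
hyposaline,hyposaline,1986,Cerbera manghas,130
hyposaline,hyposaline,1986,Talipariti tiliaceum,59
hyposaline,hyposaline,1986,Aegiceras corniculatum,33
hyposaline,hyposaline,1986,Excoecaria indica,8
hyposaline,hyposaline,1986,Tamarix dioica,8
hyposaline,hyposaline,1986,Barringtonia racemosa,7
hyposaline,hyposaline,1986,Ceriops decandra,4
hyposaline,hyposaline,1986,Sonneratia caseolaris,3
hyposaline,hyposaline,1986,Intsia bijuga,2
hyposaline,hyposaline,1986,Lannea coromandelica,2
hyposaline,hyposaline,1986,Xylocarpus granatum,1
hyposaline,hyposaline,1986,Pongamia pinnata,1
hyposaline,hyposaline,1986,Syzygium fruticosum,1
hyposaline,hyposaline,1986,Hypobathrum racemosum,0
hyposaline,hyposaline,1986,Salacia chinensis,0
hyposaline,hyposaline,1986,Rhizophora mucronata,0
hyposaline,hyposaline,1986,Lumnitzera racemosa,0
hyposaline,hyposaline,2014,Excoecaria agallocha,8634
hyposaline,hyposaline,2014,Heritiera fomes,8253
hyposaline,hyposaline,2014,Avicennia officinalis,193
hyposaline,hyposaline,2014,Sonneratia apetala,116
hyposaline,hyposaline,2014,Amoora cucullata,337
hyposaline,hyposaline,2014,Bruguiera sexangula,339
hyposaline,hyposaline,2014,Xylocarpus moluccensis,297
hyposaline,hyposaline,2014,Cynometra ramiflora,14
hyposaline,hyposaline,2014,Cerbera manghas,21
hyposaline,hyposaline,2014,Talipariti tiliaceum,31
hyposaline,hyposaline,2014,Aegiceras corniculatum,15
hyposaline,hyposaline,2014,Excoecaria indica,4
hyposaline,hyposaline,2014,Tamarix dioica,3
hyposaline,hyposaline,2014,Barringtonia racemosa,0
hyposaline,hyposaline,2014,Ceriops decandra,258
hyposaline,hyposaline,2014,Sonneratia caseolaris,0
hyposaline,hyposaline,2014,Intsia bijuga,3
hyposaline,hyposaline,2014,Lannea coromandelica,0
hyposaline,hyposaline,2014,Xylocarpus granatum,9
hyposaline,hyposaline,2014,Pongamia pinnata,2
hyposaline,hyposaline,2014,Syzygium fruticosum,1
hyposaline,hyposaline,2014,Hypobathrum racemosum,3
hyposaline,hyposaline,2014,Salacia chinensis,0
hyposaline,hyposaline,2014,Rhizophora mucronata,0
hyposaline,hyposaline,2014,Lumnitzera racemosa,0
mesosaline,mesosaline,1986,Excoecaria agallocha,7338
mesosaline,mesosaline,1986,Heritiera fomes,7754
mesosaline,mesosaline,1986,Avicennia officinalis,1
mesosaline,mesosaline,1986,Sonneratia apetala,0
mesosaline,mesosaline,1986,Amoora cucullata,51
mesosaline,mesosaline,1986,Bruguiera sexangula,1
mesosaline,mesosaline,1986,Xylocarpus moluccensis,38
mesosaline,mesosaline,1986,Cynometra ramiflora,71
mesosaline,mesosaline,1986,Cerbera manghas,0
mesosaline,mesosaline,1986,Talipariti tiliaceum,0
mesosaline,mesosaline,1986,Aegiceras corniculatum,0
mesosaline,mesosaline,1986,Excoecaria indica,0
mesosaline,mesosaline,1986,Tamarix dioica,0
mesosaline,mesosaline,1986,Barringtonia racemosa,0
mesosaline,mesosaline,1986,Ceriops decandra,20
mesosaline,mesosaline,1986,Sonneratia caseolaris,0
mesosaline,mesosaline,1986,Intsia bijuga,0
mesosaline,mesosaline,1986,Lannea coromandelica,0
mesosaline,mesosaline,1986,Xylocarpus granatum,14
mesosaline,mesosaline,1986,Pongamia pinnata,0
mesosaline,mesosaline,1986,Syzygium fruticosum,0
mesosaline,mesosaline,1986,Hypobathrum racemosum,0
mesosaline,mesosaline,1986,Salacia chinensis,12
mesosaline,mesosaline,1986,Rhizophora mucronata,0
mesosaline,mesosaline,1986,Lumnitzera racemosa,3
mesosaline,mesosaline,2014,Excoecaria agallocha,9301
mesosaline,mesosaline,2014,Heritiera fomes,5998
mesosaline,mesosaline,2014,Avicennia officinalis,0
mesosaline,mesosaline,2014,Sonneratia apetala,0
mesosaline,mesosaline,2014,Amoora cucullata,33
mesosaline,mesosaline,2014,Bruguiera sexangula,1
mesosaline,mesosaline,2014,Xylocarpus moluccensis,41
mesosaline,mesosaline,2014,Cynometra ramiflora,19
mesosaline,mesosaline,2014,Cerbera manghas,0
mesosaline,mesosaline,2014,Talipariti tiliaceum,0
mesosaline,mesosaline,2014,Aegiceras corniculatum,0
mesosaline,mesosaline,2014,Excoecaria indica,0
mesosaline,mesosaline,2014,Tamarix dioica,0
mesosaline,mesosaline,2014,Barringtonia racemosa,0
mesosaline,mesosaline,2014,Ceriops decandra,1098
mesosaline,mesosaline,2014,Sonneratia caseolaris,0
mesosaline,mesosaline,2014,Intsia bijuga,0
mesosaline,mesosaline,2014,Lannea coromandelica,0
mesosaline,mesosaline,2014,Xylocarpus granatum,12
mesosaline,mesosaline,2014,Pongamia pinnata,0
mesosaline,mesosaline,2014,Syzygium fruticosum,0
mesosaline,mesosaline,2014,Hypobathrum racemosum,4
mesosaline,mesosaline,2014,Salacia chinensis,0
mesosaline,mesosaline,2014,Rhizophora mucronata,1
mesosaline,mesosaline,2014,Lumnitzera racemosa,1
hypersaline,hypersaline,1986,Excoecaria agallocha,9505
hypersaline,hypersaline,1986,Heritiera fomes,1215
hypersaline,hypersaline,1986,Avicennia officinalis,6
hypersaline,hypersaline,1986,Sonneratia apetala,5
hypersaline,hypersaline,1986,Amoora cucullata,57
hypersaline,hypersaline,1986,Bruguiera sexangula,4
hypersaline,hypersaline,1986,Xylocarpus moluccensis,76
hypersaline,hypersaline,1986,Cynometra ramiflora,0
hypersaline,hypersaline,1986,Cerbera manghas,0
hypersaline,hypersaline,1986,Talipariti tiliaceum,0
hypersaline,hypersaline,1986,Aegiceras corniculatum,0
hypersaline,hypersaline,1986,Excoecaria indica,0
hypersaline,hypersaline,1986,Tamarix dioica,0
hypersaline,hypersaline,1986,Barringtonia racemosa,0
hypersaline,hypersaline,1986,Ceriops decandra,257
hypersaline,hypersaline,1986,Sonneratia caseolaris,0
hypersaline,hypersaline,1986,Intsia bijuga,0
hypersaline,hypersaline,1986,Lannea coromandelica,0
hypersaline,hypersaline,1986,Xylocarpus granatum,16
hypersaline,hypersaline,1986,Pongamia pinnata,0
hypersaline,hypersaline,1986,Syzygium fruticosum,0
hypersaline,hypersaline,1986,Hypobathrum racemosum,0
hypersaline,hypersaline,1986,Salacia chinensis,0
hypersaline,hypersaline,1986,Rhizophora mucronata,0
hypersaline,hypersaline,1986,Lumnitzera racemosa,0
hypersaline,hypersaline,2014,Excoecaria agallocha,11558
hypersaline,hypersaline,2014,Heritiera fomes,1009
hypersaline,hypersaline,2014,Avicennia officinalis,4
hypersaline,hypersaline,2014,Sonneratia apetala,3
hypersaline,hypersaline,2014,Amoora cucullata,41
hypersaline,hypersaline,2014,Bruguiera sexangula,5
hypersaline,hypersaline,2014,Xylocarpus moluccensis,69
hypersaline,hypersaline,2014,Cynometra ramiflora,0
hypersaline,hypersaline,2014,Cerbera manghas,0
hypersaline,hypersaline,2014,Talipariti tiliaceum,0
hypersaline,hypersaline,2014,Aegiceras corniculatum,0
hypersaline,hypersaline,2014,Excoecaria indica,0
hypersaline,hypersaline,2014,Tamarix dioica,0
hypersaline,hypersaline,2014,Barringtonia racemosa,0
hypersaline,hypersaline,2014,Ceriops decandra,1669
hypersaline,hypersaline,2014,Sonneratia caseolaris,0
hypersaline,hypersaline,2014,Intsia bijuga,0
hypersaline,hypersaline,2014,Lannea coromandelica,0
hypersaline,hypersaline,2014,Xylocarpus granatum,9
hypersaline,hypersaline,2014,Pongamia pinnata,0
hypersaline,hypersaline,2014,Syzygium fruticosum,0
hypersaline,hypersaline,2014,Hypobathrum racemosum,0
hypersaline,hypersaline,2014,Salacia chinensis,0
hypersaline,hypersaline,2014,Rhizophora mucronata,0
hypersaline,hypersaline,2014,Lumnitzera racemosa,0
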