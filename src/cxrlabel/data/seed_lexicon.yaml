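# Seed lexicon for Vietnamese chest X-ray report labeling.
#
# keywords: example abnormality phrases per anatomical region class, plus
# findings outside the four regions ("other").  "x/y" marks a left/right
# alternation; "(...)" marks an abbreviation of the preceding words.  Both
# are expanded at load time.
#
# normal_templates: SYNTHETIC stand-ins for a hospital's no-findings report
# templates (deployed template inventories are site-specific and not
# public).  Eleven fixed phrasings, each asserting a normal study.
normal_templates:
  - "Tim và phổi trong giới hạn bình thường"
  - "Không thấy tổn thương khu trú nhu mô phổi hai bên"
  - "Bóng tim không to, trung thất cân đối"
  - "Hai trường phổi sáng đều, không thấy bất thường"
  - "Góc sườn hoành hai bên nhọn, vòm hoành bình thường"
  - "Thành ngực và khung xương lồng ngực không thấy bất thường"
  - "Hình ảnh X quang ngực thẳng trong giới hạn bình thường"
  - "Không phát hiện hình ảnh bất thường trên phim chụp"
  - "Nhu mô phổi hai bên sáng đều, rốn phổi không đậm"
  - "Màng phổi hai bên không dày, không tràn dịch"
  - "Chỉ số tim ngực trong giới hạn bình thường"
keywords:
  chest_wall:
    - "Gãy xương"          # bone fracture
    - "Thưa xương"         # osteoporosis
    - "Tiêu xương"         # bone resorption
  pleura:
    - "Dày màng phổi trái/phải"                 # pleural thickening
    - "Mờ góc sườn hoành màng phổi trái/phải"   # costophrenic angle blunting
    - "Tù góc sườn hoành trái/phải"             # loss of costophrenic angle
  parenchyma:
    - "Dày thành phế quản"          # bronchial wall thickening
    - "Dày tổ chức kẽ"              # interstitial thickening
    - "Dải mờ giữa phổi trái/phải"  # mid-lung opacity
  cardio:
    - "Quai động mạch chủ (đmc) vồng"  # prominent aortic arch
    - "Hình tim trái/phải to"          # cardiomegaly
    - "Giãn cung thất trái/phải"       # ventricular arch dilatation
  other:
    - "Liềm hơi dưới vòm hoành trái/phải"  # free air under the diaphragm
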