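>RepA_1 |type=RepA |subtype=RepA-1 |source=synthetic
YLRPDIHIAYQELKFRNGVATTIKERTADRLKPKGMRATGSLSPFGQTSAQEVQRRGFQV
LVLRKTTEDGSIEMCALRNVAGYVFCIIFPKNLKTPTSEQCMEVFTTLCSMVDQLLKNRK
SGSFPELQIHSADPTLRRNKEPKNEEEHLDALAKAPGGADETALKRTGVLNRQLEVAGRI
YNTKESALNPKAGESDYDKEARADKFSLRPMDVVSVASDQKLPLL
>RepA_2 |type=RepA |subtype=RepA-2 |source=synthetic
DLRPDIIIVYQELKFRPGVATYIKERTADRLKGKGMRATGSYSPFGDCSAQAVQRRVFQV
LVLCKTREDGPGEMCALRNVAGYVFCIIFPKNYKTPTSEQCMEVFKTLCSMVDQLLKNRP
RGSFGELQIHSADPTLRRNKEPKNEEEHLDAWVKAPGGADETALKDTGVLKRQLEVAGRI
YNTKSSALNPKNGESDYDKMARADKMSLRPAFVVSVASDQNLELK
>RepB_1 |type=RepB |subtype=RepB-1 |source=synthetic
VLQGYSNNECWGIAANYGNLSDNKLFGDLNNFTLFTRVRLTLSRPLHEITGDVLFFATRH
GKRVNGSPYLGMTEKSTKKKWFYGFQLSHEGVLMRAYQCVVMVLPLLGERFCYRIEIGVI
QESVMGMLAKGTVLSLDLAELNSLKGHEDNKQESLLSRAEKRLLEEHKVPIFYLGVDDDQ
EANIICLMMIGYQPQNNTGWGAPRMGASTTAAPKGATPSEVPSTKDVAYQGPETSLAWVL
YTGSNGTLYYLESKLDKVGPPFMGATVDRWLRRVAAAAQQFDKFINLNY
>RepB_2 |type=RepB |subtype=RepB-2 |source=synthetic
VNQGYSNNECWGIAANYNNLPDNKLFGSLHNFTLFTRVRHTYSRPLHEITGDVLFFATRH
GHRVNGSPYLGMTCKVTKKKWFYGPQLSLEGAYMRAYQCVVMVLCLLGERFCIRINIGVI
QEGVMRMLAKGTVLSLDLAELNPLKTHTDNKQESLLSEAEKRLLEEHKVGIFYGGVDDDQ
EANIICLMMIGYQGQNNKQWPAPRMGADTGYAPKGAAPSEVPSPKEVPYQGPETSLAWVL
YTGSNYTLYKLESKLDKVGPPFMGATVGFWLRRVAAAAQSFDEFINLNK
>RepABC_1 |type=RepABC |subtype=RepABC-1 |source=synthetic
SKIIVQEMEQENYPCEAEYEMRTVMQKFQKEKALSMARTKVSPQLVAMAAYGSQCLHNFV
ITQYEYNASFGGTYLGVEPDEKWFLAEDKGPLRIKRLVKASKNKYHIKLSLPDESQYGIA
EDFNPNNPEEVAFSKKAQIYGAPGEGSVNTTITRALSYCKSYIFGEISKTCFNGTDVEVK
NLQFALSLPAKQLESRIPSKESFNNFQRQDATTSLLSRTFPVNYRILAESHILYAVCLLG
NRKNDGFAFETFSARQRNFRAFQGLQPP
>RepABC_2 |type=RepABC |subtype=RepABC-2 |source=synthetic
SKIIVQEMEQEDYPCEAEYEMRTVMQKRQKEKALSMIRTKVSPQLVACAHYGSQCLHYFF
ITAYEYNASMGGTYDGVEPQKKWFLAEDFGILRQLSLVKASKNKYHIKLSGPDPSQYGIA
ENFNPNVPPAVAFSKKAQIYGAPGEGSVNTHITRALDYCKSYIFCLISKYCFNGTDVEVK
NLAEALSLPAKQLRSRIESKQSFNQFQRQDATFSLLSRTFPVNYRICAESLILIAVCLWG
NRKNTGFAFETFSARQRNFRAFQGLQPP
>DnaA-like_1 |type=DnaA-like |subtype=DnaA-like-1 |source=synthetic
TMPVIKSAQCEAFMCDPLKNTTDLTCSSAPISIENNLYEYGEHGGDGGMCTANNYNAQLT
LEIFYLGNNSLFCAPDFSSPILSSEQAALTTASISDVKTAIQVPSPGRRTSKIAAVGTGY
LSVVNRMGGLQCHSREQVDVAEDESVITLAIVRVGSSLGYFMAAQIEQTPLFIDKPDEAQ
TKGFKAKGTVNFSGYPGLTANIPAKNPDTTRAMGDLSGKAANLEVYLQNSMDLVQLLENE
HNGFDHDEVS
>DnaA-like_2 |type=DnaA-like |subtype=DnaA-like-2 |source=synthetic
TPPVTKSAQCEAFMCQPLVNTNDLTCSSAFISIELNLYEYGEHGGDGGMGTATNYNAQYT
LEIFYKGNGSLFCAPYFSSPILSSQQAALTTASISTVKTAIQVPSPGRRTIKIAAVGTGY
LSVVNRMGGLQCHSRMQVDVAEDESVITLALVQVGTSLGYFVAAGIEQTPCFIDKPQEAQ
TKGYYAKGTVWFSGYPNLWANIPAKNPYTTRAMMDLSGKAANLESYLQNSMDLVQLARNE
FMGFDHDEDS
>RepL_1 |type=RepL |subtype=RepL-1 |source=synthetic
AKQMEDLLGNPMATTTQGHFDEANGPSSAFAHDDGMEGTLLALPPANLVVITPGACGAST
SRIQEKKGTIDKSASADLDEKLMFCAGVPCGRADLLSLNGDYRYGGSTVPVLFVGGSAAE
LGTLDHLTSTIYTKTKKLKILLLFYYSRTSLQADAYRNDLSEGGVAVSEQVDLLNSAVLG
GHAEDVVLMGEGPAPKEGGCERRVLFVSGRLLILSRLNDDEEADGMNGDIFHFSFTPYSF
E
>RepL_2 |type=RepL |subtype=RepL-2 |source=synthetic
AKQMEDLLGNPMATTTQGHFDEAEGPSCAFAGDDGMMGTLLALPPACMVVITPGACGEST
SRIQEKKGTYDKSARADLDESLVFCMGVPCGRADHLWLNGDKRYGGVTVPVLFVGNSHAE
MGTLFHLNITIYHKTKKLKILLLFYYKRTSLQAPAYRNDLSEGGVAVSEQYYLFNSARLG
GKAEDVVLMGEGPAPDEGGCERRVLFVSGRLLILEGLNDDEEADGMNGDIFFFSSTPYSS
E
>RepC_soli_1 |type=RepC_soli |subtype=RepC_soli-1 |source=synthetic
LVAGEGACANVWRANKPYGATLTASVELRMVGVHGGVVQVATYNSGLLFDYTPGAHIPTG
DEAKPAGTRIWSCHDLREPVEESLGREAFAKAWPSYGMMNYPTVPVAVCDGADVAKYMEF
QQMWNIFSKIDTQALDGQVPTACVGQFFIFGDKKLTKDKTMLANRVYPKQKLLLLRKAPM
CALVKRKQKAAQVDEALNRLNAFPGFMTVDPTLSIRTKKIKRVILLVLTFSETRPIHERD
TVAKGQRAAKLYGKLHLVSRAR
>RepC_soli_2 |type=RepC_soli |subtype=RepC_soli-2 |source=synthetic
LGAGEGACCNVWRANKPYGATTTSSVELRMVGVHGGVVQVALYNSGLLFDYTPGAHIPTG
EEAKELMTWIDSCQDLREKVEESLGREAFAKAWPRYRMMNYPTVPVAVCQGADVTVYMEF
QRMWGIQSKIDTQALDGQVPTACVGQFFIFKDKKLTKDKTMLGVRVYPKQKLLLLRTAPM
CALVKRIQKAAQVDEALNRDGAFPGFMRVDPTLSIGTKKIKRVSILKLTFSWGRPVHERD
TGAKGQRAAKHEGKLHLVSRAR
>RepQ_1 |type=RepQ |subtype=RepQ-1 |source=synthetic
SLHPPAKKSETIVIMLIFIQESLSAVLGMTDENRGKNSLVESSEDKNSDSLGDIDRKEDD
IDSMAQPLMDKDAKTGKNYRQMDVTRRGKAEPVAKNRMNLELKFASVDYLFGDWQGYPTL
RSENYGGEFHQPANWHQSNTRGNSPRYTLVLQDVSQVVRTTLKYVMRENINADECDNKFN
VWHGLQKGLMMAKLNMLNGISQDATVEINLISMAACAGYGLGHTSSVVKPATTMLMELVS
MGSQSDIVPNKHLTPFITLANSEGCDPAETDRIRHLLGAWAYKPDRASTALVSD
>RepQ_2 |type=RepQ |subtype=RepQ-2 |source=synthetic
SLMPQAKKSETIVIGLISIQENLSAVLGMTDENRGKNSLVCSSEDKNSDSLGDIDRKEHD
MDSMAQGLMDKDAKTGKNYRQMDVTRRGKTEPVAKNRMNLETYVASVDYLFGDWGGYPTL
RSENYHAEFHQPANWHRMNTHGNSPDYGVVIQDVSQVVRPTLKSVMRYNINADECDNKNN
VWHGLQKILMMLKLNMLNGISQIATVEINWISMAACAGTGLGHTVSVVSPATTMLMELVS
MGSFSDIVENKHLTPFHWLANSEGCDPAKTDRVRWLLGAWAYKPDRLSTALVAR
>RepY_1 |type=RepY |subtype=RepY-1 |source=synthetic
WARKKMSVVLPEETINDDISSSNLEANTIANKNLVIKFKFKSDRACDYHIKFVRIRIQKP
PREILASMQYPMNKEWHEYKAAAVVGVDLDVQCSLNGVYLGHENEFINAEETPPSKTTYY
VGFVLALSNRTPRLITNSGRLYGPISTCNTNFALNYDTQIERGPVFRQPALEGKLPDTSR
SPAYNVVTDVPVVELFLTRPAGLMYLLLSKVPYIIKAYLTGQFSILYCAQLYLIKEANLF
LLIMFVFLNLGPAGMGPNEGLPLLRNFSRHPTGPLRRRHTEAEKDTP
>RepY_2 |type=RepY |subtype=RepY-2 |source=synthetic
WARKKMSVVLYEETINDDIHSKNSEANTIANKNLVIKFKFKCDRAPKYHIKFVRIRSQKP
PREILHMMQYPKNKEWFGYKAAAVAGVDLDVQCSLNGVYLTHANEFINAEETPKSKTTYY
VGFTLALSNRTPRDITNSGRLYGPISNSNKNFALNYQTQNHRGPVFRQVAKEGKQWDTSR
SPAYNYVTDVPVVELFLVRPAGLMYLYLSKWYYIIWAYNTGQFQILYCAKLYLIQEANLE
LLIMFVFLNLGPAGKGPNEGLWLLRNFSRHPTGPLRRRKTEAEKDTP
>RepW_1 |type=RepW |subtype=RepW-1 |source=synthetic
TLRDLAQYLDDEENAESDVSGDGARRQGICKGEGRGLCFVSKHKQYETVLNPGCGSHGEE
LIDAELDFQWAGGYDMYLIFISLESGRADVAYKLSLKYDTIIGKIFLSLALLHPAGNADL
QEEHSTVSSKKMANAMIEKQIAADPGALVLDVSPAEELAAKLRTQAPRDPEIISAYPQVP
LPRKDATHLRERMVNHQLKYSPHPSPIMHAKKGQFDKLQPTNTPVGISSLSLSTDNDNDV
PIENIGIGIEELPVESTPVGKDLLKESPVI
>RepW_2 |type=RepW |subtype=RepW-2 |source=synthetic
TLRDNAQYLDDEENAESDVSGDGARRQGIYKFEGRGSCFVSKGKQYEMMLDRHCGSTGEE
LIDAELDFQWAGDYDMYLIFISLESGRADVAYKLSLKYDTIMGKIFPSLHCLHPAGNADL
QEEGYTVSSKKMSNANIALQPAADPGALVCDRSPAEELARKLRTQAPRDPWIYSAYPQVP
GPRKDATHLRVRIHNHQLKYSPHPSPIMHAKKGQFDKLQPINSPGGESSLWLSTDNDNDV
PIENIGIGIEELPMESHPVGKDLGKESPVI
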